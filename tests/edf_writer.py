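"""Reference EDF writer used only to build read-path test fixtures.

Implements the EDF header/record layout directly from the format's field
table so the package's EDF *reader* is exercised against an independent
producer. 16-bit quantization over the physical range bounds the
round-trip error at phys_range / 32767.
"""

import numpy as np


def write_edf(path, signals, fs, labels, phys_range_uv=1000.0):
    signals = np.asarray(signals, dtype=float)
    n_ch, n_samp = signals.shape
    assert len(labels) == n_ch
    spr = int(fs)  # one-second data records
    n_rec = n_samp // spr
    assert n_rec * spr == n_samp, "signal length must be a whole number of records"

    def pad(s, n):
        b = str(s).encode("ascii")
        assert len(b) <= n
        return b + b" " * (n - len(b))

    hdr = b"".join(
        [
            pad("0", 8),
            pad("X X X X", 80),
            pad("Startdate 01-JAN-2020 X X X", 80),
            pad("01.01.20", 8),
            pad("00.00.00", 8),
            pad(256 * (1 + n_ch), 8),
            pad("", 44),
            pad(n_rec, 8),
            pad(1, 8),
            pad(n_ch, 4),
        ]
    )
    hdr += b"".join(pad(lab, 16) for lab in labels)
    hdr += b"".join(pad("AgAgCl electrode", 80) for _ in labels)
    hdr += b"".join(pad("uV", 8) for _ in labels)
    hdr += b"".join(pad(-phys_range_uv, 8) for _ in labels)
    hdr += b"".join(pad(phys_range_uv, 8) for _ in labels)
    hdr += b"".join(pad(-32767, 8) for _ in labels)
    hdr += b"".join(pad(32767, 8) for _ in labels)
    hdr += b"".join(pad("", 80) for _ in labels)
    hdr += b"".join(pad(spr, 8) for _ in labels)
    hdr += b"".join(pad("", 32) for _ in labels)

    dig = np.clip(
        np.round(signals / phys_range_uv * 32767), -32767, 32767
    ).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(hdr)
        for r in range(n_rec):
            for c in range(n_ch):
                fh.write(dig[c, r * spr : (r + 1) * spr].tobytes())
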