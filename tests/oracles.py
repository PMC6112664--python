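"""Independent brute-force oracles shared between test modules."""

import numpy as np


def dense_lstsq_weights(source, target, kh, kw):
    """Slice-GRAPPA calibration assembled as one dense linear system.

    Explicit loops over interior positions and kernel offsets, solved
    with ``lstsq`` — independent of the production solver.
    """
    nc, ny, nx = source.shape
    rows = []
    for y in range(kh // 2, ny - kh // 2):
        for x in range(kw // 2, nx - kw // 2):
            row = []
            for c in range(nc):
                for dy in range(-(kh // 2), kh // 2 + 1):
                    for dx in range(-(kw // 2), kw // 2 + 1):
                        row.append(source[c, y + dy, x + dx])
            rows.append(row)
    a = np.array(rows)
    weights = np.empty((target.shape[0], nc, kh, kw), dtype=complex)
    for c in range(target.shape[0]):
        b = np.array([target[c, y, x]
                      for y in range(kh // 2, ny - kh // 2)
                      for x in range(kw // 2, nx - kw // 2)])
        w, *_ = np.linalg.lstsq(a, b, rcond=None)
        weights[c] = w.reshape(nc, kh, kw)
    return weights
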