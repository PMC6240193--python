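"""Compiled float32 inner loop for online network training.

The math mirrors :class:`mhc2lig.network.NetworkModel` exactly (sigmoid
hidden and output layers, squared-error loss, core = arg-max offset with
smallest-offset tie-break, burn-in restriction to hydrophobic P1); an
agreement test pins the two implementations together. All randomness is
drawn outside the kernel so that results are a deterministic function of the
pre-drawn index sequences.
"""
from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def train_steps(X, row_start, row_count, p1_hydro, has_hydro, targets, is_el,
                w_in, b_in, w_out_ba, b_out_ba, w_out_el, b_out_el,
                inst_seq, lr, burn_in):
    """Run one training iteration: one online gradient step per entry of
    ``inst_seq`` (instance indices, already balanced between data types).

    Weight arrays are updated in place; the scalar output biases are passed
    as 1-element arrays. ``burn_in`` restricts core selection to
    hydrophobic-P1 offsets for peptides that have one.
    """
    h = w_in.shape[0]
    d = w_in.shape[1]
    hid = np.empty(h, dtype=np.float32)
    hbest = np.empty(h, dtype=np.float32)

    for s in range(inst_seq.shape[0]):
        i = inst_seq[s]
        el = is_el[i]
        start = row_start[i]
        cnt = row_count[i]
        restrict = burn_in and has_hydro[i]

        best_r = -1
        best_y = np.float32(-1.0)
        for o in range(cnt):
            r = start + o
            if restrict and not p1_hydro[r]:
                continue
            for j in range(h):
                acc = b_in[j]
                for k in range(d):
                    acc += w_in[j, k] * X[r, k]
                hid[j] = np.float32(1.0) / (np.float32(1.0) + np.exp(-acc))
            if el:
                acc = b_out_el[0]
                for j in range(h):
                    acc += w_out_el[j] * hid[j]
            else:
                acc = b_out_ba[0]
                for j in range(h):
                    acc += w_out_ba[j] * hid[j]
            y = np.float32(1.0) / (np.float32(1.0) + np.exp(-acc))
            if y > best_y:
                best_y = y
                best_r = r
                for j in range(h):
                    hbest[j] = hid[j]

        t = np.float32(targets[i])
        d_out = (best_y - t) * best_y * (np.float32(1.0) - best_y)
        if el:
            for j in range(h):
                d_h = d_out * w_out_el[j] * hbest[j] * (np.float32(1.0) - hbest[j])
                w_out_el[j] -= lr * d_out * hbest[j]
                g = lr * d_h
                for k in range(d):
                    w_in[j, k] -= g * X[best_r, k]
                b_in[j] -= lr * d_h
            b_out_el[0] -= lr * d_out
        else:
            for j in range(h):
                d_h = d_out * w_out_ba[j] * hbest[j] * (np.float32(1.0) - hbest[j])
                w_out_ba[j] -= lr * d_out * hbest[j]
                g = lr * d_h
                for k in range(d):
                    w_in[j, k] -= g * X[best_r, k]
                b_in[j] -= lr * d_h
            b_out_ba[0] -= lr * d_out
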