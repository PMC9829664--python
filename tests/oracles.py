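"""Independent brute-force oracles shared by the unit and acceptance tests.

These deliberately avoid the library code paths they check: dilation is
shift-and-or over enumerated ball offsets, components are counted by flood
fill, and the gap definition is evaluated literally with set arithmetic.
"""

from itertools import combinations, product

import numpy as np


def enumerate_ball_offsets(r: int) -> set[tuple[int, int, int]]:
    """Integer triples with squared Euclidean norm <= r^2."""
    return {
        (x, y, z)
        for x, y, z in product(range(-r, r + 1), repeat=3)
        if x * x + y * y + z * z <= r * r
    }


def shift_no_wrap(data: np.ndarray, offset) -> np.ndarray:
    """Shift with zero fill (no wrap-around), matching clipped dilation."""
    out = np.zeros_like(data)
    src, dst = [], []
    for o, n in zip(offset, data.shape):
        if o >= 0:
            src.append(slice(0, n - o))
            dst.append(slice(o, n))
        else:
            src.append(slice(-o, n))
            dst.append(slice(0, n + o))
    out[tuple(dst)] = data[tuple(src)]
    return out


def brute_force_dilate(data: np.ndarray, r: int) -> np.ndarray:
    out = np.zeros_like(data)
    for offset in enumerate_ball_offsets(r):
        out |= shift_no_wrap(data, offset)
    return out


def aux_oracle(frag_data: list[np.ndarray], r: int) -> np.ndarray:
    """Literal evaluation of the fracture-gap definition:
    union over fragment pairs of intersected dilations, minus the bone."""
    dil = [brute_force_dilate(f, r) for f in frag_data]
    acc = np.zeros_like(frag_data[0])
    for k, l in combinations(range(len(frag_data)), 2):
        acc |= dil[k] & dil[l]
    bone = np.zeros_like(frag_data[0])
    for f in frag_data:
        bone |= f
    return acc & ~bone


def iou_bruteforce(a: np.ndarray, b: np.ndarray) -> float:
    """Loop-free independent IoU on boolean masks."""
    inter = 0
    union = 0
    for va, vb in zip(a.ravel(), b.ravel()):
        if va and vb:
            inter += 1
        if va or vb:
            union += 1
    return 1.0 if union == 0 else inter / union
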