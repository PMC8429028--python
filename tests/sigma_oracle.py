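"""Literal set-based oracle for the component-overlap confusion rules.

Independent of the package implementation: connected components come from
a hand-written BFS flood fill and the TP/FP/FN rules are applied verbatim
on python sets of (row, col) tuples.  Used only to cross-check
``funduseg.evaluation.classify_pixels``.
"""

from collections import deque

import numpy as np

NEIGHBORS_4 = ((1, 0), (-1, 0), (0, 1), (0, -1))
NEIGHBORS_8 = NEIGHBORS_4 + ((1, 1), (1, -1), (-1, 1), (-1, -1))


def flood_components(mask: np.ndarray, connectivity: int = 8) -> list[set]:
    """BFS flood-fill connected components as sets of (row, col)."""
    nbrs = NEIGHBORS_8 if connectivity == 8 else NEIGHBORS_4
    H, W = mask.shape
    seen = np.zeros((H, W), dtype=bool)
    comps = []
    for r0 in range(H):
        for c0 in range(W):
            if mask[r0, c0] and not seen[r0, c0]:
                comp = set()
                q = deque([(r0, c0)])
                seen[r0, c0] = True
                while q:
                    r, c = q.popleft()
                    comp.add((r, c))
                    for dr, dc in nbrs:
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < H and 0 <= cc < W and mask[rr, cc] and not seen[rr, cc]:
                            seen[rr, cc] = True
                            q.append((rr, cc))
                comps.append(comp)
    return comps


def sigma_classify(det_mask: np.ndarray, truth_mask: np.ndarray, sigma: float,
                   connectivity: int = 8) -> dict:
    """Apply the overlap rules literally; returns pixel sets and counts."""
    det_mask = np.asarray(det_mask) > 0
    truth_mask = np.asarray(truth_mask) > 0
    d_comps = flood_components(det_mask, connectivity)
    g_comps = flood_components(truth_mask, connectivity)
    D = set().union(*d_comps) if d_comps else set()
    G = set().union(*g_comps) if g_comps else set()

    tp = D & G
    for Di in d_comps:
        if len(Di & G) / len(Di) > sigma:
            tp |= Di
    for Gj in g_comps:
        if len(Gj & D) / len(Gj) > sigma:
            tp |= Gj

    fp = set()
    for Di in d_comps:
        if not (Di & G):
            fp |= Di
        elif len(Di & G) / len(Di) <= sigma:
            fp |= Di - G
    fn = set()
    for Gj in g_comps:
        if not (Gj & D):
            fn |= Gj
        elif len(Gj & D) / len(Gj) <= sigma:
            fn |= Gj - D

    # a pixel meeting a TP rule is TP regardless of the others
    fp -= tp
    fn -= tp
    H, W = det_mask.shape
    return {
        "TP": tp, "FP": fp, "FN": fn,
        "counts": (len(tp), len(fp), len(fn), H * W - len(tp) - len(fp) - len(fn)),
    }
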