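"""Naive independent oracles used to cross-check the implementation.

Deliberately written with plain Python data structures (sets, BFS) and no
image-processing library calls, so they share no code path with the
package under test.
"""

from collections import deque


def flood_fill_components(mask, connectivity=8):
    """Connected components by breadth-first flood fill.

    Returns a list of pixel-coordinate sets, one per component, in no
    particular order.
    """
    h, w = mask.shape
    if connectivity == 8:
        steps = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                 if (dr, dc) != (0, 0)]
    else:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    seen = set()
    components = []
    for r in range(h):
        for c in range(w):
            if not mask[r, c] or (r, c) in seen:
                continue
            comp = set()
            queue = deque([(r, c)])
            seen.add((r, c))
            while queue:
                cr, cc = queue.popleft()
                comp.add((cr, cc))
                for dr, dc in steps:
                    nr, nc = cr + dr, cc + dc
                    if (
                        0 <= nr < h and 0 <= nc < w
                        and mask[nr, nc] and (nr, nc) not in seen
                    ):
                        seen.add((nr, nc))
                        queue.append((nr, nc))
            components.append(comp)
    return components


def pixel_set_agreement(test_mask, ref_mask, eval_mask):
    """Agreement metrics from explicit pixel sets.

    Returns (fp_pct, fn_pct, precision, sensitivity, f1) in percent, or
    None when the class is empty in both masks.
    """
    ev = {(r, c) for r, c in zip(*eval_mask.nonzero())}
    t = {(r, c) for r, c in zip(*test_mask.nonzero())} & ev
    ref = {(r, c) for r, c in zip(*ref_mask.nonzero())} & ev
    tp, fp, fn = len(t & ref), len(t - ref), len(ref - t)
    if tp + fp + fn == 0:
        return None
    precision = 100.0 * tp / (tp + fp) if tp + fp else 0.0
    sensitivity = 100.0 * tp / (tp + fn) if tp + fn else 0.0
    f1 = (
        2 * precision * sensitivity / (precision + sensitivity)
        if precision + sensitivity
        else 0.0
    )
    return (100.0 * fp / len(ev), 100.0 * fn / len(ev), precision, sensitivity, f1)


def transitive_merge_count(distances_um, threshold_um=500.0):
    """Cluster count under the transitive closure of pairwise distance < t.

    ``distances_um`` maps index pairs (i, j) to boundary distances; every
    pair of the n items must be present (i < j).
    """
    items = set()
    for i, j in distances_um:
        items.update((i, j))
    clusters = [{i} for i in sorted(items)]
    changed = True
    while changed:
        changed = False
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                linked = any(
                    distances_um[tuple(sorted((i, j)))] < threshold_um
                    for i in clusters[a]
                    for j in clusters[b]
                )
                if linked:
                    clusters[a] |= clusters[b]
                    del clusters[b]
                    changed = True
                    break
            if changed:
                break
    return len(clusters)
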