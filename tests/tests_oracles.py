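"""Independent brute-force oracles shared by the test modules."""

import numpy as np


def flood_fill_boxes(mask, connectivity=8):
    """Component bounding boxes by pure-python BFS flood fill.

    Returns ``((cmin, rmin), (cmax, rmax))`` per component, sorted by the
    (row, column) of the top-left corner — the same ordering contract as
    ``pipelines.extract_rois``, against which it is compared.
    """
    mask = np.asarray(mask, bool)
    rows, cols = mask.shape
    seen = np.zeros_like(mask)
    if connectivity == 8:
        steps = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1),
                 (1, 0), (1, 1)]
    else:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    boxes = []
    for r in range(rows):
        for c in range(cols):
            if not mask[r, c] or seen[r, c]:
                continue
            stack, members = [(r, c)], []
            seen[r, c] = True
            while stack:
                cr, cc = stack.pop()
                members.append((cr, cc))
                for dr, dc in steps:
                    nr, nc = cr + dr, cc + dc
                    if 0 <= nr < rows and 0 <= nc < cols and \
                            mask[nr, nc] and not seen[nr, nc]:
                        seen[nr, nc] = True
                        stack.append((nr, nc))
            rs = [m[0] for m in members]
            cs = [m[1] for m in members]
            boxes.append(((min(cs), min(rs)), (max(cs), max(rs))))
    boxes.sort(key=lambda box: (box[0][1], box[0][0]))
    return boxes
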