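"""Plain per-pixel reference implementation of the candidate evaluation.

This is the naive triple loop — every eligible pixel, every quarter, every
angle — written directly from the scalar condition functions.  It exists as
the independent check that the vectorised detector in
:mod:`redlesion.detection` is bit-identical to the definition; it is never
used on the production path.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .detection import (
    CandidateMap,
    DetectionParams,
    assemble_lesions,
    evaluate_quarter,
)

__all__ = ["reference_candidate_map", "reference_detect"]


def reference_candidate_map(g: np.ndarray, fov: Optional[np.ndarray],
                            p: DetectionParams) -> CandidateMap:
    """Candidate maps via the naive per-pixel / per-quarter / per-angle loop."""
    g = np.asarray(g, dtype=np.float64)
    m, n = g.shape
    eligible = np.ones((m, n), dtype=bool) if fov is None else fov.astype(bool)
    q = {k: np.zeros((m, n), dtype=bool) for k in (1, 2, 3, 4)}
    for i in range(m):
        for j in range(n):
            if not eligible[i, j]:
                continue
            q1 = evaluate_quarter(g, i, j, 1, p)
            q2 = evaluate_quarter(g, i, j, 2, p)
            q[1][i, j] = q1
            q[2][i, j] = q2
            if p.use_skip_optimization:
                q[4][i, j] = False if q1 else evaluate_quarter(g, i, j, 4, p)
                q[3][i, j] = False if q2 else evaluate_quarter(g, i, j, 3, p)
            else:
                q[4][i, j] = evaluate_quarter(g, i, j, 4, p)
                q[3][i, j] = evaluate_quarter(g, i, j, 3, p)
    return CandidateMap(q1=q[1], q2=q[2], q3=q[3], q4=q[4])


def reference_detect(g: np.ndarray, fov: Optional[np.ndarray],
                     p: DetectionParams) -> tuple[CandidateMap, np.ndarray]:
    """Candidate maps and assembled lesion mask from the reference loop."""
    cmap = reference_candidate_map(g, fov, p)
    mask = assemble_lesions(g, cmap, fov, p)
    return cmap, mask
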