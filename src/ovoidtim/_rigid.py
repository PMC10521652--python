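"""Closed-form least-squares rigid superposition (Kabsch, via SVD)."""

from __future__ import annotations

import numpy as np

__all__ = ["kabsch"]


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rotation/translation mapping ``mobile`` onto ``reference``.

    Returns ``(R, t, rmsd)`` with ``R`` a proper rotation (det +1) such
    that ``R @ x + t`` least-squares-aligns the mobile points onto the
    reference points.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("selections must be matching (n, 3) arrays")
    if len(P) < 3:
        raise ValueError("need at least 3 points")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    moved = (R @ P.T).T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=1))))
    return R, t, rmsd
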