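"""Ensemble statistics about an unbiased mean structure.

The mean structure of an NMR ensemble is usually defined by superposing all
conformers on an arbitrarily chosen reference and averaging coordinates,
which biases the result toward that reference.  The unbiased alternative
implemented here averages the inter-atomic *distance matrix* over the
ensemble — a quantity that needs no superposition at all — and back-projects
the averaged matrix into Cartesian space by classical scaling
(Torgerson/Gower multidimensional scaling): double-centre the squared
distances into a Gram matrix, take the top three eigenvectors scaled by the
square roots of their eigenvalues.  Because an averaged distance matrix is
generally non-Euclidean, eigenvalues beyond rank three may be negative; they
are reported so the embedding quality can be inspected.  Classical scaling
is blind to chirality, so the mirror image with the lower Kabsch RMSD to the
first conformer is chosen.

Ensemble RMSDs are then computed by Kabsch-superposing each conformer onto
that mean.  Both the mean and the root-mean-square over per-model RMSDs are
reported, as the two summaries in common use.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure_io import Conformer, Ensemble, Selection, select_coords

__all__ = [
    "MeanStructure",
    "RmsdReport",
    "kabsch",
    "average_distance_matrix",
    "back_project",
    "unbiased_mean",
    "ensemble_rmsd",
    "per_residue_rmsd",
    "fragment_rmsd",
    "representative_model",
]


@dataclass
class MeanStructure:
    coords: np.ndarray  # (n, 3), centroid at origin, Å
    eigenvalues: np.ndarray  # descending spectrum of the centred Gram matrix
    chirality_flipped: bool


@dataclass
class RmsdReport:
    per_model_rmsd: np.ndarray  # Å, one per conformer
    ensemble_rmsd_mean: float  # arithmetic mean over models
    ensemble_rmsd_rms: float  # root-mean-square over models
    selection: Selection


def kabsch(
    X: np.ndarray, Y: np.ndarray, weights: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of Y onto X (least-squares, proper rotation).

    Returns ``(rotation, translation, rmsd)`` such that ``Y @ R.T + t``
    minimises the (optionally weighted) RMSD to ``X``.  The rotation is
    guaranteed proper (det = +1) by the usual sign correction on the smallest
    singular value.

    Raises
    ------
    ValueError
        On shape mismatch, fewer than 3 points, or a degenerate (collinear)
        point set for which the rotation is not unique.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape or X.ndim != 2 or X.shape[1] != 3:
        raise ValueError(f"expected matching (n, 3) arrays, got {X.shape} and {Y.shape}")
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points for a unique superposition")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be a non-negative n-vector with positive sum")
        w = w / w.sum()
    cx = w @ X
    cy = w @ Y
    Xc = X - cx
    Yc = Y - cy
    H = (Yc * w[:, None]).T @ Xc
    U, s, Vt = np.linalg.svd(H)
    # collinear sets leave the rotation about the line undetermined
    if s[1] < 1e-10 * max(s[0], 1e-300):
        raise ValueError("degenerate (collinear) point set: superposition not unique")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cx - R @ cy
    diff = (Yc @ R.T) - Xc
    rmsd = float(np.sqrt(np.sum(w * np.sum(diff**2, axis=1))))
    return R, t, rmsd


def average_distance_matrix(ensemble: Ensemble, selection: Selection) -> np.ndarray:
    """Mean over conformers of the pairwise inter-atomic distance matrix (Å)."""
    coords, _ = select_coords(ensemble, selection)
    n_models, n_atoms, _ = coords.shape
    D = np.zeros((n_atoms, n_atoms))
    for m in range(n_models):
        diff = coords[m][:, None, :] - coords[m][None, :, :]
        D += np.sqrt(np.sum(diff**2, axis=-1))
    return D / n_models


def back_project(D: np.ndarray) -> MeanStructure:
    """Embed a distance matrix into 3-D by classical scaling.

    The squared-distance matrix is double-centred into a Gram matrix whose
    top three eigenpairs give the coordinates.  For a matrix averaged over
    conformers the spectrum has negative tail eigenvalues; only the top three
    must be positive.

    Raises
    ------
    ValueError
        If ``D`` is not symmetric with a zero diagonal, or the geometry is
        degenerate below two dimensions (collinear points).  Planar sets are
        embedded with a near-zero third eigenvalue, which is reported.
    """
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-8) or not np.allclose(np.diag(D), 0.0, atol=1e-8):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    n = D.shape[0]
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ (D**2) @ J
    B = (B + B.T) / 2  # clean round-off asymmetry before eigh
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]
    scale = float(np.max(np.abs(eigval))) if n else 0.0
    if n < 3 or eigval[1] <= 1e-9 * max(scale, 1.0):
        raise ValueError("fewer than 2 positive eigenvalues: geometry is degenerate")
    # planar sets have λ3 ≈ 0; clamp round-off negatives before the sqrt
    coords = eigvec[:, :3] * np.sqrt(np.maximum(eigval[:3], 0.0))
    coords -= coords.mean(axis=0)
    return MeanStructure(coords=coords, eigenvalues=eigval, chirality_flipped=False)


def unbiased_mean(ensemble: Ensemble, selection: Selection) -> MeanStructure:
    """Unbiased mean structure: average distance matrix, back-projected.

    Classical scaling cannot distinguish a structure from its mirror image,
    so of the two enantiomers the one with the lower Kabsch RMSD to the first
    conformer is returned (a deterministic choice; for any real ensemble the
    correct hand wins by a wide margin).
    """
    if ensemble.n_models < 2:
        raise ValueError("unbiased mean needs at least 2 conformers")
    D = average_distance_matrix(ensemble, selection)
    mean = back_project(D)
    coords_ref, _ = select_coords(ensemble, selection)
    ref = coords_ref[0]
    mirrored = mean.coords * np.array([1.0, 1.0, -1.0])
    _, _, rmsd_direct = kabsch(ref, mean.coords)
    _, _, rmsd_mirror = kabsch(ref, mirrored)
    if rmsd_mirror < rmsd_direct:
        return MeanStructure(coords=mirrored, eigenvalues=mean.eigenvalues, chirality_flipped=True)
    return mean


def ensemble_rmsd(ensemble: Ensemble, selection: Selection) -> RmsdReport:
    """Per-model Kabsch RMSD to the unbiased mean, with ensemble summaries."""
    mean = unbiased_mean(ensemble, selection)
    coords, _ = select_coords(ensemble, selection)
    per_model = np.array([kabsch(mean.coords, coords[m])[2] for m in range(coords.shape[0])])
    return RmsdReport(
        per_model_rmsd=per_model,
        ensemble_rmsd_mean=float(per_model.mean()),
        ensemble_rmsd_rms=float(np.sqrt(np.mean(per_model**2))),
        selection=selection,
    )


def per_residue_rmsd(ensemble: Ensemble, selection: Selection) -> dict[int, float]:
    """RMS deviation from the unbiased mean per residue, after a global fit.

    Each conformer is superposed on the unbiased mean over the whole
    selection; the quoted per-residue value is the RMS over that residue's
    selected atoms and all models.
    """
    mean = unbiased_mean(ensemble, selection)
    coords, labels = select_coords(ensemble, selection)
    sq_sum: dict[int, float] = {}
    count: dict[int, int] = {}
    for m in range(coords.shape[0]):
        R, t, _ = kabsch(mean.coords, coords[m])
        fitted = coords[m] @ R.T + t
        d2 = np.sum((fitted - mean.coords) ** 2, axis=1)
        for (res_seq, _name), val in zip(labels, d2):
            sq_sum[res_seq] = sq_sum.get(res_seq, 0.0) + float(val)
            count[res_seq] = count.get(res_seq, 0) + 1
    return {r: float(np.sqrt(sq_sum[r] / count[r])) for r in sorted(sq_sum)}


def fragment_rmsd(conformer: Conformer, sel_a: Selection, sel_b: Selection) -> float:
    """Kabsch RMSD between two equal-sized fragments of one conformer.

    Atoms are matched in selection order, so the two selections must resolve
    to the same atom count (e.g. the backbones of the two CXXCXXC motifs).
    """
    ens = Ensemble(conformers=[conformer])
    ca, _ = select_coords(ens, sel_a)
    cb, _ = select_coords(ens, sel_b)
    if ca.shape[1] != cb.shape[1]:
        raise ValueError(
            f"fragment selections resolve to different atom counts: "
            f"{ca.shape[1]} vs {cb.shape[1]}"
        )
    return kabsch(ca[0], cb[0])[2]


def representative_model(ensemble: Ensemble, selection: Selection) -> int:
    """Index (0-based) of the conformer closest to the unbiased mean."""
    report = ensemble_rmsd(ensemble, selection)
    return int(np.argmin(report.per_model_rmsd))
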