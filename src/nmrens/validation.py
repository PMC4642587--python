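"""Structure validation: Ramachandran statistics and zinc-site geometry.

Ramachandran classification uses a four-region (most favoured / additional
allowed / generously allowed / disallowed) 10°x10° grid over the φ/ψ torus
in the style of the Morris et al. maps used by PROCHECK, shipped as a
packaged text table so the region definitions live in exactly one place.
Glycine, proline and chain-terminal residues are excluded from the
statistics, following the same convention.

Zinc-site checks measure the tetrahedral Cys4-Zn coordination geometry
(S-Zn bonds, S-Zn-S angles, and the cysteine side-chain angles that appear
in the structural restraints) and compare them against target values.  The
assignment of cysteines to the two zinc clusters of a CXXC domain is
recovered from the ensemble itself by average-linkage clustering of the
mean SG-SG distance matrix — mirroring how the assignment is established
experimentally from calculations run without zinc restraints.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .structure_io import Conformer, Ensemble, Selection

__all__ = [
    "ZincRestraintSet",
    "RamaPoint",
    "RamaSummary",
    "ClusterAssignment",
    "dihedral",
    "rama_classify",
    "rama_summary",
    "zinc_geometry",
    "check_restraints",
    "assign_cys_clusters",
]

REGIONS = ("most_favoured", "additional", "generous", "disallowed")
_REGION_CHAR = {"F": "most_favoured", "A": "additional", "G": "generous", "D": "disallowed"}


@dataclass(frozen=True)
class ZincRestraintSet:
    """Target geometry of a Cys4-Zn site, with per-item tolerances.

    Defaults are the canonical tetrahedral-thiolate restraint values
    (S-Zn 2.3 Å; Cα-Cβ-S 114.3558°; Cβ-S-Zn 109.5°; Hβ-Cβ-S 107.9185°;
    S-Zn-S 109.5°).  Tolerances default to 0.1 Å for bonds and 5° for angles.
    """

    s_zn_bond: float = 2.3
    ca_cb_s_angle: float = 114.3558
    cb_s_zn_angle: float = 109.5000
    hb_cb_s_angle: float = 107.9185
    s_zn_s_angle: float = 109.5000
    bond_tolerance: float = 0.1
    angle_tolerance: float = 5.0

    def __post_init__(self) -> None:
        for name in ("s_zn_bond", "ca_cb_s_angle", "cb_s_zn_angle", "hb_cb_s_angle",
                     "s_zn_s_angle", "bond_tolerance", "angle_tolerance"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class RamaPoint:
    res_seq: int
    phi: float | None
    psi: float | None
    region: str  # one of REGIONS or "excluded"


@dataclass
class RamaSummary:
    counts: dict[str, int]
    percentages: dict[str, float]  # over classifiable residues
    n_classifiable: int
    n_excluded: int

    @property
    def favoured_plus_additional(self) -> float:
        return self.percentages["most_favoured"] + self.percentages["additional"]


@dataclass
class ClusterAssignment:
    partition: tuple[frozenset[int], frozenset[int]]
    silhouette: float


def dihedral(p1, p2, p3, p4) -> float:
    """Signed IUPAC torsion angle p1-p2-p3-p4 in degrees, in (−180, 180]."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    norm_b2 = np.linalg.norm(b2)
    if np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9 or norm_b2 < 1e-12:
        raise ValueError("collinear points: torsion undefined")
    m1 = np.cross(b2 / norm_b2, n1)
    angle = math.degrees(math.atan2(float(m1 @ n2), float(n1 @ n2)))
    return 180.0 if angle <= -180.0 + 1e-12 else angle


def _load_grid() -> np.ndarray:
    """36x36 region grid; rows ψ ascending from −180, columns φ ascending."""
    text = resources.files("nmrens.data").joinpath("rama_grid.txt").read_text()
    rows = [line for line in text.splitlines() if line and not line.startswith("#")]
    grid = np.array([list(row) for row in rows])
    if grid.shape != (36, 36):
        raise RuntimeError(f"malformed Ramachandran grid: shape {grid.shape}")
    return grid


_GRID_CACHE: np.ndarray | None = None


def _grid() -> np.ndarray:
    global _GRID_CACHE
    if _GRID_CACHE is None:
        _GRID_CACHE = _load_grid()
    return _GRID_CACHE


def rama_classify(phi: float, psi: float, res_name: str, position: str = "internal") -> str:
    """Region of a (φ, ψ) pair; Gly/Pro and chain termini are ``excluded``.

    ``position`` is ``internal``, ``n_term`` or ``c_term`` — terminal
    residues lack one of the two torsions and are excluded by convention.
    """
    if res_name.upper() in ("GLY", "PRO") or position != "internal":
        return "excluded"
    i_phi = int((phi % 360.0) // 10.0)  # 0 at φ = -180 after shift below
    i_psi = int((psi % 360.0) // 10.0)
    # map [0, 360) bins back to [-180, 180) ordering
    i_phi = (i_phi + 18) % 36
    i_psi = (i_psi + 18) % 36
    return _REGION_CHAR[str(_grid()[i_psi, i_phi])]


def backbone_torsions(conformer: Conformer) -> dict[int, tuple[float | None, float | None]]:
    """φ/ψ per residue from a conformer's N/CA/C atoms (author numbering)."""
    bb: dict[int, dict[str, np.ndarray]] = {}
    for a in conformer.atoms:
        if a.name in ("N", "CA", "C"):
            bb.setdefault(a.res_seq, {})[a.name] = np.asarray(a.coords)
    out: dict[int, tuple[float | None, float | None]] = {}
    for res in sorted(bb):
        prev, this, nxt = bb.get(res - 1), bb[res], bb.get(res + 1)
        phi = psi = None
        if prev is not None and len(this) == 3 and "C" in prev:
            phi = dihedral(prev["C"], this["N"], this["CA"], this["C"])
        if nxt is not None and len(this) == 3 and "N" in nxt:
            psi = dihedral(this["N"], this["CA"], this["C"], nxt["N"])
        out[res] = (phi, psi)
    return out


def rama_points(conformer: Conformer, sequence: dict[int, str],
                selection: Selection | None = None) -> list[RamaPoint]:
    torsions = backbone_torsions(conformer)
    points = []
    for res, (phi, psi) in torsions.items():
        if selection is not None and not selection.contains(res):
            continue
        name = sequence.get(res, "UNK")
        if phi is None or psi is None:
            points.append(RamaPoint(res, phi, psi, "excluded"))
        else:
            points.append(RamaPoint(res, phi, psi, rama_classify(phi, psi, name)))
    return points


def rama_summary(ensemble: Ensemble, selection: Selection | None = None) -> RamaSummary:
    """Region percentages pooled over all conformers and selected residues."""
    counts = {r: 0 for r in REGIONS}
    n_excluded = 0
    for conformer in ensemble.conformers:
        for pt in rama_points(conformer, ensemble.sequence, selection):
            if pt.region == "excluded":
                n_excluded += 1
            else:
                counts[pt.region] += 1
    n_class = sum(counts.values())
    if n_class == 0:
        raise ValueError("no classifiable residues in selection")
    percentages = {r: 100.0 * counts[r] / n_class for r in REGIONS}
    return RamaSummary(counts=counts, percentages=percentages,
                       n_classifiable=n_class, n_excluded=n_excluded)


# ---------------------------------------------------------------------------
# zinc-site geometry


def _angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in degrees."""
    v1, v2 = a - b, c - b
    cosang = float(v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    return math.degrees(math.acos(max(-1.0, min(1.0, cosang))))


@dataclass
class ZincSiteGeometry:
    s_zn_bonds: dict[int, float]  # per Cys res_seq, Å
    s_zn_s_angles: dict[tuple[int, int], float]  # per Cys pair, degrees
    ca_cb_s_angles: dict[int, float]
    cb_s_zn_angles: dict[int, float]
    hb_cb_s_angles: dict[tuple[int, str], float]  # per (Cys, Hβ name); empty without H


def zinc_geometry(conformer: Conformer, cys_residues: list[int],
                  zn_res_seq: int | None = None) -> ZincSiteGeometry:
    """Measure the coordination geometry of one Cys4-Zn site.

    ``zn_res_seq`` selects among several ZN heteroatoms; by default the Zn
    closest to the centroid of the four SG atoms is used.  Missing SG/Zn
    atoms are a hard error listing what is absent.
    """
    atoms: dict[tuple[int, str], np.ndarray] = {}
    zincs: dict[int, np.ndarray] = {}
    for a in conformer.atoms:
        if a.res_name == "ZN" or (a.element.upper() == "ZN"):
            zincs[a.res_seq] = np.asarray(a.coords)
        elif a.res_seq in cys_residues:
            atoms[(a.res_seq, a.name)] = np.asarray(a.coords)
    missing = [f"SG of Cys {r}" for r in cys_residues if (r, "SG") not in atoms]
    if not zincs:
        missing.append("Zn atom")
    if missing:
        raise ValueError("missing atoms: " + ", ".join(missing))
    sg = {r: atoms[(r, "SG")] for r in cys_residues}
    if zn_res_seq is not None:
        if zn_res_seq not in zincs:
            raise ValueError(f"missing atoms: Zn {zn_res_seq}")
        zn = zincs[zn_res_seq]
    else:
        centroid = np.mean(list(sg.values()), axis=0)
        zn = min(zincs.values(), key=lambda p: float(np.linalg.norm(p - centroid)))

    bonds = {r: float(np.linalg.norm(sg[r] - zn)) for r in cys_residues}
    szs = {}
    for i, r1 in enumerate(cys_residues):
        for r2 in cys_residues[i + 1:]:
            szs[(r1, r2)] = _angle(sg[r1], zn, sg[r2])
    ca_cb_s, cb_s_zn, hb_cb_s = {}, {}, {}
    for r in cys_residues:
        ca, cb = atoms.get((r, "CA")), atoms.get((r, "CB"))
        if ca is not None and cb is not None:
            ca_cb_s[r] = _angle(ca, cb, sg[r])
        if cb is not None:
            cb_s_zn[r] = _angle(cb, sg[r], zn)
            for hb_name in ("HB1", "HB2", "HB3", "1HB", "2HB", "3HB"):
                hb = atoms.get((r, hb_name))
                if hb is not None:
                    hb_cb_s[(r, hb_name)] = _angle(hb, cb, sg[r])
    return ZincSiteGeometry(bonds, szs, ca_cb_s, cb_s_zn, hb_cb_s)


@dataclass
class RestraintViolation:
    item: str
    measured: float
    target: float
    deviation: float
    tolerance: float


@dataclass
class RestraintReport:
    violations: list[RestraintViolation]
    n_checked: int

    @property
    def n_violations(self) -> int:
        return len(self.violations)


def check_restraints(geom: ZincSiteGeometry, restraints: ZincRestraintSet | None = None
                     ) -> RestraintReport:
    """Compare measured site geometry against targets at stated tolerances."""
    r = restraints or ZincRestraintSet()
    checks: list[tuple[str, float, float, float]] = []
    for res, d in geom.s_zn_bonds.items():
        checks.append((f"S-Zn bond Cys{res}", d, r.s_zn_bond, r.bond_tolerance))
    for (r1, r2), ang in geom.s_zn_s_angles.items():
        checks.append((f"S-Zn-S Cys{r1}/Cys{r2}", ang, r.s_zn_s_angle, r.angle_tolerance))
    for res, ang in geom.ca_cb_s_angles.items():
        checks.append((f"CA-CB-S Cys{res}", ang, r.ca_cb_s_angle, r.angle_tolerance))
    for res, ang in geom.cb_s_zn_angles.items():
        checks.append((f"CB-S-Zn Cys{res}", ang, r.cb_s_zn_angle, r.angle_tolerance))
    for (res, hb), ang in geom.hb_cb_s_angles.items():
        checks.append((f"HB-CB-S Cys{res}:{hb}", ang, r.hb_cb_s_angle, r.angle_tolerance))
    violations = [
        RestraintViolation(item, meas, target, abs(meas - target), tol)
        for item, meas, target, tol in checks
        if abs(meas - target) > tol
    ]
    return RestraintReport(violations=violations, n_checked=len(checks))


def assign_cys_clusters(ensemble: Ensemble, cys_residues: list[int],
                        expected_split: tuple[int, int] | None = (4, 4)) -> ClusterAssignment:
    """Partition cysteines into two zinc clusters from mean SG-SG distances.

    Average-linkage hierarchical clustering on the ensemble-mean SG-SG
    distance matrix, cut at two clusters.  Two tetrahedral sites need 4+4,
    so any other split is an error reporting the offending partition
    (``expected_split=None`` disables the check).  The silhouette score
    (mean over cysteines) quantifies separation.
    """
    if ensemble.n_models < 1:
        raise ValueError("empty ensemble")
    residues = sorted(cys_residues)
    sel = Selection(tuple((r, r) for r in residues), "SG")
    from .structure_io import select_coords

    coords, labels = select_coords(ensemble, sel)
    order = [labels.index((r, "SG")) for r in residues]
    coords = coords[:, order, :]
    n = len(residues)
    if n < 2:
        raise ValueError("need at least 2 cysteines")
    D = np.zeros((n, n))
    for m in range(coords.shape[0]):
        diff = coords[m][:, None, :] - coords[m][None, :, :]
        D += np.sqrt((diff**2).sum(-1))
    D /= coords.shape[0]
    Z = linkage(squareform(D, checks=False), method="average")
    flat = fcluster(Z, t=2, criterion="maxclust")
    set1 = frozenset(r for r, c in zip(residues, flat) if c == 1)
    set2 = frozenset(r for r, c in zip(residues, flat) if c == 2)

    # mean silhouette over the two-cluster partition
    sil = []
    for i, r in enumerate(residues):
        own = set1 if r in set1 else set2
        other = set2 if r in set1 else set1
        own_idx = [residues.index(x) for x in own if x != r]
        oth_idx = [residues.index(x) for x in other]
        a = float(np.mean([D[i, j] for j in own_idx])) if own_idx else 0.0
        b = float(np.mean([D[i, j] for j in oth_idx])) if oth_idx else 0.0
        sil.append((b - a) / max(a, b) if max(a, b) > 0 else 0.0)
    score = float(np.mean(sil))

    expected = expected_split
    if expected is not None and sorted((len(set1), len(set2))) != sorted(expected):
        raise ValueError(
            f"cysteines split {len(set1)}+{len(set2)}, expected {expected}: "
            f"{sorted(set1)} | {sorted(set2)}"
        )
    return ClusterAssignment(partition=(set1, set2), silhouette=score)
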