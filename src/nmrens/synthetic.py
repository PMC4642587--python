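"""Ground-truth-known synthetic inputs for every stage of the analysis.

Three generators mirror the three kinds of experimental input:

* ideal-geometry backbone templates and Gaussian-perturbed conformer
  ensembles with a per-residue displacement profile (rigid core, flexible
  loop and termini), for the ensemble-statistics and Ramachandran code;
* tetrahedral Cys4-Zn coordination sites with controllable distortion, for
  the zinc-geometry and cluster-assignment code;
* ¹⁵N relaxation datasets computed from known model-free parameters for an
  isotropic tumbler, with Gaussian noise and optionally the underlying
  intensity-decay series, for the τm and model-free fitting code.

Every generator is a pure function of its spec (including the seed).  The
default protein emulated throughout is a 56-residue zinc-finger construct
(author numbering 167-222) with well-ordered segments 175-196 and 208-217,
a flexible loop 197-207 and flexible termini, tumbling at τm = 5.67 ns at a
¹H frequency of 600.13 MHz — the study conditions of a small CXXC domain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .modelfree import (
    DecaySeries,
    FieldConfig,
    MotionalParams,
    RelaxationRecord,
    predict_rates,
)
from .structure_io import Atom, Conformer, Ensemble

__all__ = [
    "EnsembleSpec",
    "RelaxSpec",
    "make_template",
    "make_cxxc_template",
    "perturb_ensemble",
    "make_zinc_site",
    "simulate_relaxation",
    "default_relax_spec",
    "T1_DELAYS",
    "T2_DELAYS",
]

# relaxation delay series used for the decay simulations (s)
T1_DELAYS = (0.1, 1.0, 2.0, 4.0)
T2_DELAYS = (0.017, 0.034, 0.068, 0.102, 0.136, 0.237)

# ideal backbone internal coordinates (Engh-Huber-like)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_CA_CB = 1.458, 1.525, 1.329, 1.231, 1.530
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O, _A_C_CA_CB = 111.2, 116.2, 121.7, 120.8, 110.1

HELIX_PHI, HELIX_PSI = -57.0, -47.0


def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
          bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom d given a-b-c with |c-d| = bond, angle(b,c,d), torsion(a,b,c,d)."""
    ang, tor = math.radians(angle), math.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [-bond * math.cos(ang),
         bond * math.sin(ang) * math.cos(tor),
         bond * math.sin(ang) * math.sin(tor)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


@dataclass(frozen=True)
class EnsembleSpec:
    """Recipe for a perturbed ensemble around a template conformer."""

    n_models: int
    template: Conformer
    sigma_profile: dict[int, float]  # res_seq -> displacement SD, Å
    smoothing_window: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_models < 2:
            raise ValueError("need at least 2 models")
        if any(s < 0 for s in self.sigma_profile.values()):
            raise ValueError("sigmas must be non-negative")


@dataclass(frozen=True)
class RelaxSpec:
    """Recipe for a relaxation dataset from per-residue model-free truth."""

    truth: dict[int, MotionalParams]
    cfg: FieldConfig = field(default_factory=FieldConfig)
    noise_fraction: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_fraction <= 0:
            raise ValueError("noise_fraction must be positive")


def _sample_allowed_phipsi(rng: np.random.Generator) -> tuple[float, float]:
    from .validation import rama_classify

    while True:
        phi = float(rng.uniform(-180, 180))
        psi = float(rng.uniform(-180, 180))
        if rama_classify(phi, psi, "ALA") in ("most_favoured", "additional"):
            return phi, psi


def make_template(
    n_res: int,
    motif: str = "helix",
    start_res: int = 1,
    seed: int = 0,
    flexible_ranges: tuple[tuple[int, int], ...] = (),
    res_names: dict[int, str] | None = None,
    chain: str = "A",
) -> Conformer:
    """Ideal-geometry backbone template (N, CA, C, O, CB per residue).

    ``motif``: ``helix`` uses φ = −57°, ψ = −47° throughout; ``coil`` draws
    each (φ, ψ) from the favoured/additional Ramachandran regions (seeded);
    ``mixed`` is helix except in ``flexible_ranges``, which are coil.
    Residues default to ALA; ``res_names`` overrides individual positions.
    """
    if n_res < 4:
        raise ValueError("need at least 4 residues")
    if motif not in ("helix", "coil", "mixed"):
        raise ValueError(f"unknown motif {motif!r}")
    rng = np.random.default_rng(seed)
    res_names = res_names or {}

    def angles(res_seq: int) -> tuple[float, float]:
        if motif == "helix":
            return HELIX_PHI, HELIX_PSI
        if motif == "coil":
            return _sample_allowed_phipsi(rng)
        flexible = any(lo <= res_seq <= hi for lo, hi in flexible_ranges)
        return _sample_allowed_phipsi(rng) if flexible else (HELIX_PHI, HELIX_PSI)

    residues = list(range(start_res, start_res + n_res))
    phi_psi = {r: angles(r) for r in residues}

    # seed atoms of residue 1
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([_B_N_CA, 0.0, 0.0])
    ang = math.radians(_A_N_CA_C)
    c0 = ca0 + _B_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    backbone: dict[int, dict[str, np.ndarray]] = {residues[0]: {"N": n0, "CA": ca0, "C": c0}}
    for prev, res in zip(residues, residues[1:]):
        pN, pCA, pC = (backbone[prev][k] for k in ("N", "CA", "C"))
        psi_prev = phi_psi[prev][1]
        N = _nerf(pN, pCA, pC, _B_C_N, _A_CA_C_N, psi_prev)
        CA = _nerf(pCA, pC, N, _B_N_CA, _A_C_N_CA, 180.0)  # trans peptide
        C = _nerf(pC, N, CA, _B_CA_C, _A_N_CA_C, phi_psi[res][0])
        backbone[res] = {"N": N, "CA": CA, "C": C}

    atoms: list[Atom] = []
    serial = 1
    for i, res in enumerate(residues):
        name3 = res_names.get(res, "ALA")
        bb = backbone[res]
        entries = [("N", "N", bb["N"]), ("CA", "C", bb["CA"]), ("C", "C", bb["C"])]
        if i + 1 < len(residues):
            next_n = backbone[residues[i + 1]]["N"]
            o = _nerf(next_n, bb["CA"], bb["C"], _B_C_O, _A_CA_C_O, 180.0)
        else:  # C-terminal O anti to psi of an ideal continuation
            o = _nerf(bb["N"], bb["CA"], bb["C"], _B_C_O, _A_CA_C_O, phi_psi[res][1] + 180.0)
        entries.append(("O", "O", o))
        if name3 != "GLY":
            cb = _nerf(bb["N"], bb["C"], bb["CA"], _B_CA_CB, _A_C_CA_CB, 122.55)
            entries.append(("CB", "C", cb))
            if name3 == "CYS":  # gauche(-) χ1, ideal thiol geometry
                sg = _nerf(bb["N"], bb["CA"], cb, 1.81, 114.3558, -60.0)
                entries.append(("SG", "S", sg))
        for atom_name, element, pos in entries:
            atoms.append(
                Atom(serial=serial, name=atom_name, element=element, alt_loc="",
                     res_name=name3, chain=chain, res_seq=res,
                     coords=(float(pos[0]), float(pos[1]), float(pos[2])))
            )
            serial += 1
    return Conformer(model_id=1, atoms=atoms)


#: segments of the default emulated construct (author numbering)
CXXC_RANGES = {
    "construct": (167, 222),
    "ordered_1": (175, 196),
    "ordered_2": (208, 217),
    "loop": (197, 207),
    "cys_cluster_1": (176, 179, 182, 215),
    "cys_cluster_2": (188, 191, 194, 210),
}


def make_cxxc_template(seed: int = 0) -> tuple[Conformer, dict]:
    """56-residue zinc-finger-like template (residues 167-222).

    Ordered segments 175-196 and 208-217 are helical; the 197-207 loop and
    the termini are coil.  Cysteines are placed at the canonical two-cluster
    motif positions.  Returns the conformer plus a metadata dict tagging the
    segment ranges.
    """
    cys = CXXC_RANGES["cys_cluster_1"] + CXXC_RANGES["cys_cluster_2"]
    flexible = ((167, 174), CXXC_RANGES["loop"], (218, 222))
    conf = make_template(
        56, motif="mixed", start_res=167, seed=seed,
        flexible_ranges=flexible,
        res_names={r: "CYS" for r in cys},
    )
    meta = dict(CXXC_RANGES, flexible_ranges=flexible)
    return conf, meta


def default_sigma_profile(
    rigid_sigma: float = 0.3, flexible_sigma: float = 2.0
) -> dict[int, float]:
    """Displacement profile of the default construct: rigid core, mobile rest."""
    profile = {}
    for res in range(167, 223):
        ordered = 175 <= res <= 196 or 208 <= res <= 217
        profile[res] = rigid_sigma if ordered else flexible_sigma
    return profile


def perturb_ensemble(spec: EnsembleSpec) -> Ensemble:
    """Template plus Gaussian atomic displacements, chain-smoothed per residue.

    The per-residue σ profile is smoothed with a centred moving average
    (window ``smoothing_window`` residues) so displacement amplitude varies
    coherently along the chain, then applied as iid Gaussian noise to every
    atom coordinate of the residue in every model.
    """
    rng = np.random.default_rng(spec.seed)
    residues = sorted({a.res_seq for a in spec.template.atoms})
    sigma = np.array([spec.sigma_profile.get(r, 0.0) for r in residues])
    w = spec.smoothing_window
    if w > 1:
        kernel = np.ones(w) / w
        pad = w // 2
        padded = np.concatenate([np.repeat(sigma[0], pad), sigma, np.repeat(sigma[-1], pad)])
        sigma = np.convolve(padded, kernel, mode="valid")[: len(residues)]
    sigma_of = dict(zip(residues, sigma))

    conformers = []
    for m in range(spec.n_models):
        atoms = []
        for a in spec.template.atoms:
            s = sigma_of[a.res_seq]
            shift = rng.normal(0.0, s, size=3) if s > 0 else np.zeros(3)
            atoms.append(
                Atom(serial=a.serial, name=a.name, element=a.element, alt_loc=a.alt_loc,
                     res_name=a.res_name, chain=a.chain, res_seq=a.res_seq,
                     coords=(a.coords[0] + shift[0], a.coords[1] + shift[1],
                             a.coords[2] + shift[2]))
            )
        conformers.append(Conformer(model_id=m + 1, atoms=atoms))
    sequence = {a.res_seq: a.res_name for a in spec.template.atoms}
    return Ensemble(conformers=conformers, sequence=sequence)


_TETRAHEDRON = np.array(
    [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
) / math.sqrt(3.0)


def make_zinc_site(
    s_zn: float = 2.3,
    distortion: float = 0.0,
    seed: int = 0,
    cys_residues: tuple[int, ...] = (1, 4, 7, 10),
    center: tuple[float, float, float] = (0.0, 0.0, 0.0),
    chain: str = "A",
    zn_res_seq: int = 900,
) -> Conformer:
    """Cys4-Zn site fragment: Zn + per-cysteine SG/CB/CA scaffold.

    At ``distortion = 0`` the four sulfurs sit on an exact tetrahedron at
    ``s_zn`` Å from the zinc with ideal side-chain angles (Cβ-S-Zn 109.5°,
    Cα-Cβ-S 114.3558°); positive ``distortion`` adds seeded Gaussian
    displacement of that SD (Å) to every non-Zn atom.
    """
    if s_zn <= 0:
        raise ValueError("s_zn must be positive")
    rng = np.random.default_rng(seed)
    zn = np.asarray(center, dtype=float)
    atoms = [Atom(serial=1, name="ZN", element="ZN", alt_loc="", res_name="ZN",
                  chain=chain, res_seq=zn_res_seq, coords=tuple(zn))]
    serial = 2
    for k, res in enumerate(cys_residues):
        u = _TETRAHEDRON[k]
        sg = zn + s_zn * u
        # reference frame: any unit vector not parallel to u
        ref = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
        cb = _nerf(zn + ref, zn, sg, 1.81, 109.5000, 60.0 + 30.0 * k)
        ca = _nerf(zn, sg, cb, 1.53, 114.3558, 180.0)
        positions = {"SG": sg, "CB": cb, "CA": ca}
        for name, pos in positions.items():
            if distortion > 0:
                pos = pos + rng.normal(0.0, distortion, size=3)
            atoms.append(
                Atom(serial=serial, name=name, element="S" if name == "SG" else "C",
                     alt_loc="", res_name="CYS", chain=chain, res_seq=res,
                     coords=(float(pos[0]), float(pos[1]), float(pos[2])))
            )
            serial += 1
    return Conformer(model_id=1, atoms=atoms)


def simulate_relaxation(
    spec: RelaxSpec, with_decays: bool = False
) -> list[RelaxationRecord] | tuple[list[RelaxationRecord], dict[int, dict[str, DecaySeries]]]:
    """Relaxation records from model-free truth with Gaussian noise.

    R1 and R2 get relative noise ``noise_fraction``; the NOE, being an
    intensity ratio of order one, gets absolute noise of the same magnitude.
    The quoted uncertainties equal the generating noise SDs.  With
    ``with_decays`` the per-residue T1/T2 intensity series (at the
    conventional delay lists) and the NOE intensity pair, consistent with
    the noisy rates, are returned as well.
    """
    rng = np.random.default_rng(spec.seed)
    f = spec.noise_fraction
    records: list[RelaxationRecord] = []
    decays: dict[int, dict[str, DecaySeries]] = {}
    for res in sorted(spec.truth):
        r1, r2, noe = predict_rates(spec.truth[res], spec.cfg)
        s1, s2, sn = f * r1, f * r2, f * max(abs(noe), 1.0)
        obs_r1 = max(r1 + rng.normal(0, s1), 1e-6)
        obs_r2 = max(r2 + rng.normal(0, s2), 1e-6)
        obs_noe = noe + rng.normal(0, sn)
        records.append(
            RelaxationRecord(res_seq=res, R1=obs_r1, R2=obs_r2, NOE=obs_noe,
                             sigma_R1=s1, sigma_R2=s2, sigma_NOE=sn)
        )
        if with_decays:
            i0 = 1000.0
            sigma_i = f * i0
            t1 = tuple(i0 * math.exp(-obs_r1 * t) + rng.normal(0, sigma_i) for t in T1_DELAYS)
            t2 = tuple(i0 * math.exp(-obs_r2 * t) + rng.normal(0, sigma_i) for t in T2_DELAYS)
            decays[res] = {
                "T1": DecaySeries(T1_DELAYS, t1, sigma_i),
                "T2": DecaySeries(T2_DELAYS, t2, sigma_i),
                "NOE_pair": DecaySeries((0.0, 1.0, 2.0),
                                        (i0, obs_noe * i0, i0), sigma_i),
            }
    if with_decays:
        return records, decays
    return records


def default_relax_spec(
    tau_m: float = 5.67,
    noise_fraction: float = 0.02,
    seed: int = 0,
    cfg: FieldConfig | None = None,
) -> RelaxSpec:
    """Model-free truth for the default 56-residue construct.

    Ordered residues (175-196, 208-217) are near-rigid (model 2, S² drawn
    around 0.84 ± 0.02, τe 20-50 ps) with a handful of exchange-broadened
    residues around the first cysteine cluster (model 4, R_ex 2-5 s⁻¹); the
    loop (197-207) and termini move on two timescales (model 5, S² 0.3-0.5,
    Sf² 0.7-0.85, τe 0.8-1.5 ns), which places their NOE below the 0.6
    flexibility cutoff at 600.13 MHz.
    """
    rng = np.random.default_rng(seed + 104729)
    cfg = cfg or FieldConfig()
    truth: dict[int, MotionalParams] = {}
    rex_residues = {177, 180, 183, 186}
    for res in range(167, 223):
        ordered = 175 <= res <= 196 or 208 <= res <= 217
        if ordered and res in rex_residues:
            truth[res] = MotionalParams(
                model_id=4, S2=float(np.clip(rng.normal(0.84, 0.02), 0.0, 1.0)),
                tau_m=tau_m, tau_e=float(rng.uniform(20, 50)),
                R_ex=float(rng.uniform(2.0, 5.0)))
        elif ordered:
            truth[res] = MotionalParams(
                model_id=2, S2=float(np.clip(rng.normal(0.84, 0.02), 0.0, 1.0)),
                tau_m=tau_m, tau_e=float(rng.uniform(20, 50)))
        else:
            s2 = float(rng.uniform(0.30, 0.50))
            sf2 = float(rng.uniform(0.70, 0.85))
            truth[res] = MotionalParams(
                model_id=5, S2=s2, S2_f=sf2, tau_m=tau_m,
                tau_e=float(rng.uniform(800, 1500)))
    return RelaxSpec(truth=truth, cfg=cfg, noise_fraction=noise_fraction, seed=seed)
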