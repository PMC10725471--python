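"""Seeded synthetic-data generators for every pipeline stage.

Each generator is a pure function of its parameters (seed included) and
returns the data object together with a JSON-serialisable ``truth``
dictionary recording what was planted, so recovery can be checked
without touching the generator internals.

The built-in toy fold is a 60-odd-residue helical hairpin whose residue
numbering sparsely covers 20-190, so the trigger-site residues
(Q28/L45/A46/L47/D48/R109/Y164/T172/F176), the distance-pair residues
(K21, R134, R145) and the canonical-site vertices (M79, T85, V91, K189)
all exist with the sidechain atoms their selections need.  It is a
geometric stand-in, not a physical model of BAX.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np

from .assay_models import (
    CETSA_ANCHOR_C,
    CETSA_GRADIENT_C,
    BindingIsotherm,
    DepolarizationTraces,
    DoseMatrix,
    MeltCurve,
    SECProfile,
)
from .ensemble_metrics import ConformationEnsemble
from .nmr_csp import PeakList
from .pharmacophore import (
    POLAR_OR_CHARGED,
    CompositionRule,
    FeatureKind,
    FeaturePoint,
    LigandConformer,
    PharmacophoreModel,
    enumerate_correspondences,
)
from .structure_io import AtomRecord, Structure

__all__ = [
    "toy_fold",
    "gen_peaklists",
    "gen_ensemble",
    "gen_isotherm",
    "gen_melt_curves",
    "gen_dose_matrix",
    "gen_sec_profile",
    "gen_conformer_library",
    "gen_depolarization",
]

# Sidechain heavy atoms per residue type (backbone N/CA/C/O always present).
_SIDECHAINS: dict[str, tuple[str, ...]] = {
    "ALA": ("CB",),
    "GLY": (),
    "LEU": ("CB", "CG", "CD1", "CD2"),
    "VAL": ("CB", "CG1", "CG2"),
    "THR": ("CB", "OG1", "CG2"),
    "GLN": ("CB", "CG", "CD", "OE1", "NE2"),
    "MET": ("CB", "CG", "SD", "CE"),
    "PHE": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"),
    "ARG": ("CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"),
    "ASP": ("CB", "CG", "OD1", "OD2"),
    "LYS": ("CB", "CG", "CD", "CE", "NZ"),
}

# Residues with a specific identity in the toy fold; everything else is ALA.
_SPECIAL_RESIDUES: dict[int, str] = {
    21: "LYS", 28: "GLN", 45: "LEU", 46: "ALA", 47: "LEU", 48: "ASP",
    79: "MET", 85: "THR", 91: "VAL", 109: "ARG", 134: "ARG", 145: "ARG",
    164: "TYR", 172: "THR", 176: "PHE", 189: "LYS",
}


def _toy_residue_numbers() -> list[int]:
    filler = set(range(20, 191, 4))
    return sorted(filler | set(_SPECIAL_RESIDUES))


def toy_fold() -> Structure:
    """Deterministic helical-hairpin coordinate set with full sidechains."""
    resnums = _toy_residue_numbers()
    n = len(resnums)
    half = n // 2
    atoms: list[AtomRecord] = []
    serial = 1
    for ri, resnum in enumerate(resnums):
        resname = _SPECIAL_RESIDUES.get(resnum, "ALA")
        # Ideal-helix CA trace; second leg anti-parallel, 10 A away.
        if ri < half:
            t = ri
            theta = np.deg2rad(100.0) * t
            ca = np.array([2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * t])
            axis = np.array([0.0, 0.0, 1.0])
        else:
            t = n - 1 - ri
            theta = np.deg2rad(100.0) * t + 0.7
            ca = np.array([10.0 + 2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * t])
            axis = np.array([0.0, 0.0, -1.0])
        center = np.array([0.0 if ri < half else 10.0, 0.0, ca[2]])
        u = ca - center
        u /= np.linalg.norm(u)
        tang = np.cross(axis, u)
        coords = {
            "N": ca + 0.8 * tang + 0.9 * axis,
            "CA": ca,
            "C": ca - 0.8 * tang + 0.9 * axis,
            "O": ca - 1.4 * tang + 1.6 * axis,
        }
        for k, name in enumerate(_SIDECHAINS[resname], start=1):
            # outward chain with deterministic wobble; avoids collinearity
            coords[name] = (
                ca
                + (1.0 + 1.4 * k) * u
                + 0.5 * np.sin(1.7 * k + 0.3 * ri) * tang
                + 0.4 * np.cos(2.3 * k + 0.5 * ri) * axis
            )
        for name, pos in coords.items():
            atoms.append(
                AtomRecord(
                    serial=serial,
                    atom_name=name,
                    residue_name=resname,
                    residue_number=resnum,
                    chain_id="A",
                    position=pos,
                    element="H" if name.startswith("H") else name.lstrip("0123456789")[0],
                    model_index=1,
                )
            )
            serial += 1
    return Structure(atoms=atoms, n_models=1, source_id="toy-helical-hairpin")


def gen_peaklists(
    n_residues: int = 80,
    planted_residues: Sequence[int] | None = None,
    offset_h: float = 0.05,
    offset_n: float = 0.25,
    sigma_h: float = 0.005,
    sigma_n: float = 0.025,
    absent_fraction: float = 0.05,
    seed: int = 0,
) -> tuple[PeakList, PeakList, dict]:
    """Reference and ligand-bound HSQC peak lists with planted perturbations.

    Reference shifts are drawn uniformly in realistic amide windows
    (1H 7-9.5 ppm, 15N 105-130 ppm); the bound list adds Gaussian noise
    everywhere and the stated offsets on the planted residues.  A
    fraction of non-planted residues is dropped from the bound list to
    emulate prolines/overlapped peaks.
    """
    if n_residues < 10:
        raise ValueError("need at least 10 residues")
    rng = np.random.default_rng(seed)
    residues = list(range(1, n_residues + 1))
    if planted_residues is None:
        planted_residues = list(residues[4 : 4 + max(1, n_residues // 10)])
    planted = set(planted_residues)
    if not planted <= set(residues):
        raise ValueError("planted residues outside the residue range")
    csp_offset = 0.5 * np.hypot(offset_h, offset_n / 5)
    csp_noise = 0.5 * np.hypot(sigma_h, sigma_n / 5)
    if csp_offset <= csp_noise:
        warnings.warn("planted offset is within the noise scale: undetectable by design")
    ref_entries = {
        r: (float(rng.uniform(7.0, 9.5)), float(rng.uniform(105.0, 130.0)))
        for r in residues
    }
    candidates = [r for r in residues if r not in planted]
    n_absent = int(round(absent_fraction * n_residues))
    absent = set(rng.choice(candidates, size=min(n_absent, len(candidates)), replace=False).tolist())
    bound_entries = {}
    for r in residues:
        if r in absent:
            continue
        h, nshift = ref_entries[r]
        h += float(rng.normal(0, sigma_h))
        nshift += float(rng.normal(0, sigma_n))
        if r in planted:
            sh, sn = (1.0, 1.0) if rng.random() < 0.5 else (-1.0, -1.0)
            h += sh * offset_h
            nshift += sn * offset_n
        bound_entries[r] = (h, nshift)
    truth = {
        "planted": sorted(planted),
        "absent": sorted(int(a) for a in absent),
        "offset_h": offset_h,
        "offset_n": offset_n,
    }
    return PeakList(ref_entries, "ref"), PeakList(bound_entries, "bound"), truth


def _ca_indices_of(structure: Structure) -> dict[int, int]:
    out = {}
    for i, a in enumerate(structure.model_atoms(1)):
        if a.atom_name == "CA":
            out[a.residue_number] = i
    return out


def gen_ensemble(
    base: Structure | None = None,
    n_frames: int = 100,
    sigma_per_residue: dict[int, float] | None = None,
    sigma_default: float = 0.0,
    area_vertices: tuple[int, int, int, int] = (189, 91, 85, 79),
    target_area_pct: float | None = None,
    seed: int = 0,
) -> tuple[ConformationEnsemble, dict]:
    """Ensemble of frames around a base fold with planted fluctuations.

    Per-residue isotropic Gaussian displacements of the stated amplitude
    give a known RMSF truth of sigma * sqrt(3).  When
    ``target_area_pct`` is set, the four canonical-site vertex residues
    drift linearly over the frames (their CA scaled about the common
    vertex centroid) so the mean two-triangle site area exceeds the base
    area by exactly that percentage.
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    structure = base if base is not None else toy_fold()
    model = structure.model_atoms(1)
    names = [a.atom_name for a in model]
    resnums = [a.residue_number for a in model]
    base_coords = np.stack([a.position for a in model])
    rng = np.random.default_rng(seed)
    sigmas = np.array(
        [
            (sigma_per_residue or {}).get(r, sigma_default)
            for r in resnums
        ]
    )
    frames = np.repeat(base_coords[None], n_frames, axis=0)
    noise = rng.normal(0.0, 1.0, size=frames.shape) * sigmas[None, :, None]
    frames = frames + noise
    if target_area_pct is not None:
        ca = _ca_indices_of(structure)
        try:
            vidx = [ca[r] for r in area_vertices]
        except KeyError as exc:
            raise KeyError(f"area vertex residue missing a CA atom: {exc}") from exc
        centroid = base_coords[vidx].mean(axis=0)
        # linear drift 0 -> 2*target in area, mean exactly target
        deltas = np.linspace(0.0, 2.0 * target_area_pct / 100.0, n_frames)
        for f, delta in enumerate(deltas):
            scale = np.sqrt(1.0 + delta)  # area scales with the square
            for i in vidx:
                frames[f, i] = centroid + scale * (frames[f, i] - centroid)
    truth = {
        "rmsf": {
            int(resnums[i]): float(sigmas[i] * np.sqrt(3.0))
            for i in range(len(names))
            if names[i] == "CA"
        },
        "target_area_pct": target_area_pct,
    }
    ensemble = ConformationEnsemble(frames, names, resnums)
    return ensemble, truth


def gen_isotherm(
    kd_nm: float = 560.0,
    b_max: float = 1.0,
    baseline: float = 0.0,
    n_points: int = 12,
    noise_cv: float = 0.03,
    span_decades: float = 1.5,
    seed: int = 0,
) -> tuple[BindingIsotherm, dict]:
    """One-site binding titration bracketing K_D by >=10x each side."""
    if kd_nm <= 0:
        raise ValueError("K_D must be positive")
    if n_points < 5:
        raise ValueError("need at least 5 titration points")
    rng = np.random.default_rng(seed)
    conc = np.logspace(
        np.log10(kd_nm) - span_decades, np.log10(kd_nm) + span_decades, n_points
    )
    clean = b_max * conc / (kd_nm + conc) + baseline
    response = clean * (1.0 + noise_cv * rng.normal(size=n_points))
    truth = {"K_D": kd_nm, "B_max": b_max, "baseline": baseline, "noise_cv": noise_cv}
    return BindingIsotherm(conc, response, label=f"synthetic KD={kd_nm}nM"), truth


def gen_melt_curves(
    tm_control: float = 62.0,
    delta_tm: float = 4.5,
    slope_k: float = 2.0,
    noise_cv: float = 0.02,
    gain: float = 1.0,
    seed: int = 0,
) -> tuple[MeltCurve, MeltCurve, dict]:
    """Control and ligand-treated Boltzmann melt curves on the CETSA grid.

    Sampled at the eight gradient temperatures plus the 25 C anchor.
    ``delta_tm`` is the destabilisation: treated Tm = control Tm - delta.
    """
    temps = np.array([CETSA_ANCHOR_C, *CETSA_GRADIENT_C])
    lo, hi = temps.min(), temps.max()
    tm_treated = tm_control - delta_tm
    for tm in (tm_control, tm_treated):
        if not lo < tm < hi:
            raise ValueError(f"Tm {tm} outside the temperature span")
    rng = np.random.default_rng(seed)

    def sample(tm: float) -> np.ndarray:
        clean = gain * 100.0 / (1.0 + np.exp((temps - tm) / slope_k))
        return clean * (1.0 + noise_cv * rng.normal(size=temps.size))

    control = MeltCurve(temps, sample(tm_control), label="control")
    treated = MeltCurve(temps, sample(tm_treated), label="treated")
    truth = {"Tm_control": tm_control, "Tm_treated": tm_treated, "delta_Tm": delta_tm}
    return control, treated, truth


def _hill(dose: np.ndarray, ec50: float, h: float, emax: float) -> np.ndarray:
    out = np.zeros_like(dose, dtype=float)
    nz = dose > 0
    out[nz] = emax * dose[nz] ** h / (ec50**h + dose[nz] ** h)
    return out


def gen_dose_matrix(
    doses_a: Sequence[float] | None = None,
    doses_b: Sequence[float] | None = None,
    ec50_a: float = 200.0,
    hill_a: float = 1.2,
    emax_a: float = 0.9,
    ec50_b: float = 500.0,
    hill_b: float = 1.0,
    emax_b: float = 0.8,
    synergy_delta: float = 0.0,
    noise_sd: float = 0.01,
    seed: int = 0,
) -> tuple[DoseMatrix, dict]:
    """Dose-combination grid under Bliss independence plus optional synergy.

    Single-agent effects follow Hill curves; interior cells get
    ``synergy_delta`` added on top of the independent expectation.
    Effects are clipped to [0, 1]; clipping is recorded in the truth.
    """
    da = np.array([0, 25, 50, 100, 200, 400] if doses_a is None else doses_a, dtype=float)
    db = np.array([0, 62.5, 125, 250, 500, 1000] if doses_b is None else doses_b, dtype=float)
    rng = np.random.default_rng(seed)
    fa = _hill(da, ec50_a, hill_a, emax_a)
    fb = _hill(db, ec50_b, hill_b, emax_b)
    expected = fa[:, None] + fb[None, :] - fa[:, None] * fb[None, :]
    effect = expected.copy()
    interior = np.ix_(da > 0, db > 0)
    effect[interior] += synergy_delta
    effect += noise_sd * rng.normal(size=effect.shape)
    clipped = bool(np.any(effect < 0) or np.any(effect > 1))
    effect = np.clip(effect, 0.0, 1.0)
    truth = {"synergy_delta": synergy_delta, "clipped": clipped, "noise_sd": noise_sd}
    return DoseMatrix(da, db, effect), truth


# 0.5-ml SEC fractions; windows chosen so the dimer peak (14-14.5 ml)
# falls in C3-C5 and the monomer peak (15.5-16 ml) in C6-C7 territory.
_SEC_FRACTION_STARTS = {
    "B2": 11.75, "B1": 12.25, "C1": 12.75, "C2": 13.25, "C3": 13.75,
    "C4": 14.25, "C5": 14.75, "C6": 15.25, "C7": 15.75, "C8": 16.25,
    "C9": 16.75,
}


def gen_sec_profile(
    dimer_fraction: float = 0.5,
    dimer_center_ml: float = 14.3,
    monomer_center_ml: float = 16.0,
    peak_width_ml: float = 0.2,
    total_intensity: float = 1000.0,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> tuple[SECProfile, dict]:
    """Bimodal elution profile integrated into labelled 0.5-ml fractions."""
    if not 0.0 <= dimer_fraction <= 1.0:
        raise ValueError("dimer_fraction must be in [0, 1]")
    from scipy.stats import norm

    rng = np.random.default_rng(seed)
    labels = list(_SEC_FRACTION_STARTS)
    intensity = np.zeros(len(labels))
    for i, lab in enumerate(labels):
        lo = _SEC_FRACTION_STARTS[lab]
        hi = lo + 0.5
        mass_d = norm.cdf(hi, dimer_center_ml, peak_width_ml) - norm.cdf(
            lo, dimer_center_ml, peak_width_ml
        )
        mass_m = norm.cdf(hi, monomer_center_ml, peak_width_ml) - norm.cdf(
            lo, monomer_center_ml, peak_width_ml
        )
        intensity[i] = total_intensity * (
            dimer_fraction * mass_d + (1.0 - dimer_fraction) * mass_m
        )
    if noise_cv > 0:
        intensity = np.clip(intensity * (1.0 + noise_cv * rng.normal(size=intensity.size)), 0, None)
    volumes = np.array([_SEC_FRACTION_STARTS[l] + 0.25 for l in labels])
    truth = {"dimer_fraction": dimer_fraction}
    return SECProfile(labels, intensity, volumes), truth


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )


def gen_conformer_library(
    model: PharmacophoreModel,
    n_active: int = 5,
    n_decoy: int = 95,
    jitter: float = 0.1,
    seed: int = 0,
) -> tuple[list[LigandConformer], dict]:
    """Toy screening library of planted actives and scrambled decoys.

    Actives are rule-satisfying subsets of the model's own features,
    rigidly transformed into a random ligand frame and jittered by less
    than the matching tolerance.  Decoys preserve the feature-kind
    multiset but have random geometry, verified (by correspondence
    enumeration) to admit no distance-consistent mapping of the minimum
    match size.
    """
    if jitter >= model.tolerance:
        raise ValueError("jitter must stay below the matching tolerance")
    rng = np.random.default_rng(seed)
    rule = model.rule
    by_kind: dict[str, list[int]] = {}
    for i, f in enumerate(model.features):
        by_kind.setdefault(f.kind.value, []).append(i)
    polar_idx = [i for k in POLAR_OR_CHARGED for i in by_kind.get(k, [])]
    if (
        len(by_kind.get("hydrophobic", [])) < rule.min_hydrophobic
        or len(by_kind.get("aromatic", [])) < rule.min_aromatic
        or not polar_idx
    ):
        raise ValueError("composition rule unsatisfiable from the model's features")

    def active_subset() -> list[int]:
        hyd = rng.choice(by_kind["hydrophobic"], size=rule.min_hydrophobic, replace=False)
        aro = rng.choice(by_kind["aromatic"], size=rule.min_aromatic, replace=False)
        pol = rng.choice(polar_idx, size=1, replace=False)
        return sorted(int(i) for i in np.concatenate([hyd, aro, pol]))

    conformers: list[LigandConformer] = []
    actives, decoys = [], []
    for a in range(n_active):
        subset = active_subset()
        pos = np.stack([model.features[i].position for i in subset])
        R = _random_rotation(rng)
        t = rng.uniform(-20, 20, size=3)
        pos = pos @ R.T + t + rng.normal(0, jitter, size=pos.shape)
        lid = f"active_{a:03d}"
        conformers.append(
            LigandConformer(
                lid,
                [
                    FeaturePoint(model.features[i].kind, p, f"model:{i}")
                    for i, p in zip(subset, pos)
                ],
            )
        )
        actives.append(lid)
    for d in range(n_decoy):
        subset = active_subset()
        kinds = [model.features[i].kind for i in subset]
        for _ in range(100):
            pos = rng.uniform(0, 30, size=(len(kinds), 3))
            decoy = LigandConformer(
                f"decoy_{d:03d}",
                [FeaturePoint(k, p, "decoy") for k, p in zip(kinds, pos)],
            )
            if not enumerate_correspondences(model, decoy, model.tolerance, rule.min_matched):
                break
        else:  # pragma: no cover - vanishingly unlikely
            raise RuntimeError("could not scramble a decoy away from the model")
        conformers.append(decoy)
        decoys.append(decoy.id)
    truth = {"actives": actives, "decoys": decoys, "jitter": jitter}
    return conformers, truth


def gen_depolarization(
    sample_fractions: dict[str, float] | None = None,
    n_timepoints: int = 13,
    step_min: float = 15.0,
    dmso_level: float = 1000.0,
    cccp_level: float = 300.0,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> tuple[DepolarizationTraces, dict]:
    """Mitochondrial-depolarization fluorescence time courses (0-180 min).

    Sample traces interpolate linearly (per planted fraction) between
    the solvent-only DMSO control and the fully depolarised CCCP
    control, so the planted fraction is the expected AUC-normalised
    percentage / 100.
    """
    if sample_fractions is None:
        sample_fractions = {"sample_25": 0.25, "sample_50": 0.5, "sample_75": 0.75}
    rng = np.random.default_rng(seed)
    t = np.arange(n_timepoints) * step_min
    decay = np.exp(-t / 600.0)  # slow photobleaching-like drift
    dmso = dmso_level * decay
    cccp = cccp_level * decay
    noisy = lambda y: y * (1.0 + noise_cv * rng.normal(size=y.size)) if noise_cv else y
    samples = {
        name: noisy(dmso + frac * (cccp - dmso))
        for name, frac in sample_fractions.items()
    }
    traces = DepolarizationTraces(t, samples, noisy(dmso), noisy(cccp))
    truth = {"planted_percent": {k: 100.0 * v for k, v in sample_fractions.items()}}
    return traces, truth
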