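"""Conformational-ensemble analytics.

Rigid superposition (Kabsch), per-frame RMSD, per-residue RMSF and its
relative change between ligand-bound and apo ensembles, named atom-pair
distance series, and the canonical-site area computed as the sum of two
triangles via Heron's formula.

The canonical site is the C-terminal hydrophobic groove of BAX that is
occupied by helix alpha-9 in the inactive conformer; its opening is
quantified here as the area spanned by the C-alpha atoms of residues
K189, V91, T85 and M79, decomposed into triangles K189-V91-T85 and
K189-M79-T85.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .structure_io import AtomSelection, Structure

__all__ = [
    "ConformationEnsemble",
    "AreaSpec",
    "SuperposeResult",
    "kabsch_superpose",
    "rmsd_series",
    "rmsf_per_residue",
    "delta_rmsf",
    "distance_series",
    "heron_area",
    "canonical_site_area",
    "replicate_mean_area",
]


@dataclass
class ConformationEnsemble:
    """Frames of atom coordinates sharing one atom-metadata table.

    ``coords``: (n_frames, n_atoms, 3) in Angstrom.  ``atom_names``,
    ``residue_numbers`` index the second axis.  Frame times are optional
    and carried through untouched.
    """

    coords: np.ndarray
    atom_names: list[str]
    residue_numbers: list[int]
    frame_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must be (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != len(self.atom_names):
            raise ValueError("atom metadata length does not match coords")
        if self.coords.shape[0] < 1:
            raise ValueError("ensemble needs at least one frame")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @classmethod
    def from_structure(cls, structure: Structure) -> "ConformationEnsemble":
        """Stack the models of a multi-model Structure into frames."""
        first = structure.model_atoms(1)
        names = [a.atom_name for a in first]
        resnums = [a.residue_number for a in first]
        frames = []
        for m in range(1, structure.n_models + 1):
            model = structure.model_atoms(m)
            if [a.atom_name for a in model] != names or [
                a.residue_number for a in model
            ] != resnums:
                raise ValueError(f"model {m} atom table differs from model 1")
            frames.append(np.stack([a.position for a in model]))
        return cls(np.stack(frames), names, resnums)

    def atom_indices(self, selection: AtomSelection) -> np.ndarray:
        """Indices of atoms matched by name/residue (selection chain ignored)."""
        idx = [
            i
            for i, (name, res) in enumerate(zip(self.atom_names, self.residue_numbers))
            if res == selection.residue_number
            and (
                name in selection.atom_name
                if isinstance(selection.atom_name, tuple)
                else name == selection.atom_name
            )
        ]
        if not idx:
            raise KeyError(
                f"selection residue {selection.residue_number} atom "
                f"{selection.atom_name!r} matches no ensemble atom"
            )
        return np.array(idx)


class SuperposeResult(NamedTuple):
    rotation: np.ndarray  # (3, 3), proper (det = +1)
    translation: np.ndarray  # (3,)
    rmsd: float  # Angstrom
    degenerate: bool  # True when points were (near-)collinear


def kabsch_superpose(P: np.ndarray, Q: np.ndarray) -> SuperposeResult:
    """Least-squares rigid superposition of Q onto P.

    Returns rotation R and translation t minimising RMSD(P, Q @ R.T + t).
    Reflections are corrected so the rotation is always proper.  For
    collinear (rank-deficient in two directions) point sets a
    translation-only fallback is applied and flagged.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("P and Q must both be (n, 3)")
    n = P.shape[0]
    if n < 3:
        raise ValueError("superposition needs at least 3 points")
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    H = Qc.T @ Pc
    U, S, Vt = np.linalg.svd(H)
    scale = max(S[0], 1.0)
    degenerate = S[1] / scale < 1e-9  # collinear: only one significant direction
    if degenerate:
        R = np.eye(3)
    else:
        d = np.sign(np.linalg.det(Vt.T @ U.T))
        D = np.diag([1.0, 1.0, d])
        R = Vt.T @ D @ U.T
    t = P.mean(axis=0) - Q.mean(axis=0) @ R.T
    rmsd = float(np.sqrt(np.mean(np.sum((Q @ R.T + t - P) ** 2, axis=1))))
    return SuperposeResult(R, t, rmsd, degenerate)


def apply_transform(coords: np.ndarray, result: SuperposeResult) -> np.ndarray:
    return np.asarray(coords) @ result.rotation.T + result.translation


def rmsd_series(
    ensemble: ConformationEnsemble,
    reference_frame: int = 0,
    selection_indices: np.ndarray | None = None,
) -> np.ndarray:
    """Per-frame RMSD onto a reference frame after superposition.

    Each frame is superposed onto the reference on the selection and the
    RMSD reported on the same selection.  ``selection_indices`` defaults
    to all atoms.
    """
    idx = (
        np.arange(ensemble.n_atoms)
        if selection_indices is None
        else np.asarray(selection_indices)
    )
    ref = ensemble.coords[reference_frame][idx]
    out = np.empty(ensemble.n_frames)
    for f in range(ensemble.n_frames):
        out[f] = kabsch_superpose(ref, ensemble.coords[f][idx]).rmsd
    return out


def ca_indices(ensemble: ConformationEnsemble) -> tuple[np.ndarray, list[int]]:
    """C-alpha atom indices and their residue numbers, in residue order."""
    pairs = [
        (i, r)
        for i, (n, r) in enumerate(zip(ensemble.atom_names, ensemble.residue_numbers))
        if n == "CA"
    ]
    if not pairs:
        raise KeyError("ensemble contains no CA atoms")
    idx = np.array([p[0] for p in pairs])
    resnums = [p[1] for p in pairs]
    return idx, resnums


def rmsf_per_residue(
    ensemble: ConformationEnsemble, selection_indices: np.ndarray | None = None
) -> dict[int, float]:
    """Per-residue RMSF about the mean structure (C-alpha by default).

    Frames are superposed onto the raw frame-average once and the mean is
    recomputed from the superposed frames (single iteration); RMSF_i is
    the root-mean-square displacement of atom i about that mean.
    """
    if ensemble.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    if selection_indices is None:
        idx, resnums = ca_indices(ensemble)
    else:
        idx = np.asarray(selection_indices)
        resnums = [ensemble.residue_numbers[i] for i in idx]
    X = ensemble.coords[:, idx, :]
    mean0 = X.mean(axis=0)
    aligned = np.empty_like(X)
    for f in range(X.shape[0]):
        aligned[f] = apply_transform(X[f], kabsch_superpose(mean0, X[f]))
    mean1 = aligned.mean(axis=0)
    rmsf = np.sqrt(np.mean(np.sum((aligned - mean1) ** 2, axis=2), axis=0))
    return dict(zip(resnums, rmsf.tolist()))


def delta_rmsf(
    rmsf_bound: dict[int, float], rmsf_apo: dict[int, float]
) -> dict[int, float]:
    """Relative RMSF change (bound - apo) / apo per residue.

    The apo profile is conventionally the average over apo replicate
    simulations; averaging replicate profiles is the caller's step.
    """
    if set(rmsf_bound) != set(rmsf_apo):
        raise ValueError("bound and apo RMSF cover different residue sets")
    out = {}
    for res in sorted(rmsf_bound):
        apo = rmsf_apo[res]
        if apo <= 0:
            raise ZeroDivisionError(f"apo RMSF is zero at residue {res}")
        out[res] = (rmsf_bound[res] - apo) / apo
    return out


def distance_series(
    ensemble: ConformationEnsemble,
    pair: tuple[AtomSelection, AtomSelection],
) -> np.ndarray:
    """Euclidean distance per frame between two selections.

    Multi-atom selections contribute their centroid (e.g. a carboxylate
    or guanidinium group versus a lysine zeta nitrogen).
    """
    ia = ensemble.atom_indices(pair[0])
    ib = ensemble.atom_indices(pair[1])
    a = ensemble.coords[:, ia, :].mean(axis=1)
    b = ensemble.coords[:, ib, :].mean(axis=1)
    return np.linalg.norm(a - b, axis=1)


def heron_area(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Triangle area from side lengths via Heron's formula (Angstrom^2).

    Near-degenerate triangles whose radicand rounds negative return 0.
    """
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    a = float(np.linalg.norm(p2 - p3))
    b = float(np.linalg.norm(p1 - p3))
    c = float(np.linalg.norm(p1 - p2))
    s = 0.5 * (a + b + c)
    radicand = s * (s - a) * (s - b) * (s - c)
    return float(np.sqrt(max(radicand, 0.0)))


@dataclass(frozen=True)
class AreaSpec:
    """Four vertices and the two-triangle decomposition of the site area.

    Defaults follow the canonical-site convention: C-alpha of K189, V91,
    T85 and M79 with triangles (K189, V91, T85) and (K189, M79, T85).
    """

    vertices: tuple[AtomSelection, AtomSelection, AtomSelection, AtomSelection] = (
        AtomSelection(189, "CA"),
        AtomSelection(91, "CA"),
        AtomSelection(85, "CA"),
        AtomSelection(79, "CA"),
    )
    triangles: tuple[tuple[int, int, int], tuple[int, int, int]] = ((0, 1, 2), (0, 3, 2))

    def __post_init__(self) -> None:
        if len(set(self.vertices)) != 4:
            raise ValueError("the four vertex selections must be distinct")


@dataclass
class AreaResult:
    area_series: np.ndarray  # Angstrom^2 per frame
    mean: float
    percent_change: float | None = None  # vs reference ensemble mean


def canonical_site_area(
    ensemble: ConformationEnsemble,
    spec: AreaSpec = AreaSpec(),
    reference: "ConformationEnsemble | None" = None,
) -> AreaResult:
    """Per-frame two-triangle site area, its mean, and percent change.

    ``percent_change`` = 100 * (mean(ensemble) - mean(reference)) /
    mean(reference) when a reference (typically apo) ensemble is given.
    """
    pts = np.stack(
        [ensemble.coords[:, ensemble.atom_indices(v), :].mean(axis=1) for v in spec.vertices],
        axis=1,
    )  # (n_frames, 4, 3)
    series = np.array(
        [
            sum(heron_area(frame[t[0]], frame[t[1]], frame[t[2]]) for t in spec.triangles)
            for frame in pts
        ]
    )
    mean = float(series.mean())
    pct = None
    if reference is not None:
        ref_mean = canonical_site_area(reference, spec).mean
        pct = 100.0 * (mean - ref_mean) / ref_mean
    return AreaResult(series, mean, pct)


def replicate_mean_area(
    ensembles: Sequence[ConformationEnsemble], spec: AreaSpec = AreaSpec()
) -> float:
    """Mean of per-ensemble mean areas (no frame pooling across replicates)."""
    if not ensembles:
        raise ValueError("need at least one ensemble")
    return float(np.mean([canonical_site_area(e, spec).mean for e in ensembles]))
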