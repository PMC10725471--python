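"""Dimer-interface pharmacophore modelling and conformer-library screening.

A pharmacophore model is a set of typed 3D feature points placed on the
trigger-site residues of the inactive BAX dimer interface: hydrophobic
points mimicking the Q28/L45/L47/T172 sidechains, an aromatic point on
F176, positive and negative ionic points on R109 and D48, and
hydrogen-bond donor/acceptor points on the A46 mainchain and the Y164
hydroxyl.  A ligand conformer matches when at least ``min_matched`` of
its own typed features can be rigidly superposed onto model features of
compatible type within a distance tolerance, subject to a composition
rule (three hydrophobic points, one aromatic, and - for five-point
matches - one hydrogen-bonding or charged point).

Matching proceeds by correspondence enumeration with distance-geometry
pruning (two features can only pair if every pairwise distance on the
model side agrees with the ligand side within twice the tolerance),
followed by Kabsch superposition of each surviving correspondence and
selection of the lowest-RMSD valid mapping.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .ensemble_metrics import kabsch_superpose, apply_transform
from .structure_io import AtomSelection, Structure, selection_centroid

__all__ = [
    "FeatureKind",
    "FeaturePoint",
    "CompositionRule",
    "PharmacophoreModel",
    "LigandConformer",
    "MatchResult",
    "build_model",
    "default_feature_spec",
    "enumerate_correspondences",
    "match_conformer",
    "screen_library",
    "load_library_tsv",
    "save_library_tsv",
    "save_model_yaml",
    "load_model_yaml",
]

POLAR_OR_CHARGED = frozenset({"donor", "acceptor", "positive", "negative"})


class FeatureKind(str, enum.Enum):
    hydrophobic = "hydrophobic"
    aromatic = "aromatic"
    positive = "positive"
    negative = "negative"
    donor = "donor"
    acceptor = "acceptor"


@dataclass(frozen=True)
class FeaturePoint:
    kind: FeatureKind
    position: np.ndarray  # (3,) Angstrom
    source_tag: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", FeatureKind(self.kind))
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"feature {self.source_tag!r}: bad position")
        object.__setattr__(self, "position", pos)


@dataclass(frozen=True)
class CompositionRule:
    """Minimum feature-role counts a valid match must contain.

    ``polar_or_charged_from_size``: matches of at least this many points
    must additionally contain ``min_polar_or_charged + 1`` ... i.e. the
    extra point beyond the hydrophobic/aromatic core must be a
    donor/acceptor/positive/negative feature.  With the defaults a
    4-point match needs 3 hydrophobic + 1 aromatic, and a 5-point match
    needs one hydrogen-bonding or charged point on top.
    """

    min_matched: int = 4
    min_hydrophobic: int = 3
    min_aromatic: int = 1
    min_polar_or_charged: int = 0
    polar_or_charged_from_size: int = 5

    def __post_init__(self) -> None:
        if self.min_matched < 4:
            raise ValueError("min_matched must be >= 4")

    def satisfied(self, kinds: Sequence[FeatureKind]) -> bool:
        n = len(kinds)
        if n < self.min_matched:
            return False
        counts = {"hydrophobic": 0, "aromatic": 0, "polar_or_charged": 0}
        for k in kinds:
            if k == FeatureKind.hydrophobic:
                counts["hydrophobic"] += 1
            elif k == FeatureKind.aromatic:
                counts["aromatic"] += 1
            if k.value in POLAR_OR_CHARGED:
                counts["polar_or_charged"] += 1
        need_polar = self.min_polar_or_charged
        if n >= self.polar_or_charged_from_size:
            need_polar = max(need_polar, 1)
        return (
            counts["hydrophobic"] >= self.min_hydrophobic
            and counts["aromatic"] >= self.min_aromatic
            and counts["polar_or_charged"] >= need_polar
        )


@dataclass
class PharmacophoreModel:
    features: list[FeaturePoint]
    tolerance: float = 2.0  # Angstrom matching radius
    rule: CompositionRule = field(default_factory=CompositionRule)
    allow_aromatic_as_hydrophobic: bool = False

    def __post_init__(self) -> None:
        if len(self.features) < 4:
            raise ValueError("a pharmacophore model needs at least 4 features")
        pos = np.stack([f.position for f in self.features])
        d = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
        if np.any(d[np.triu_indices(len(pos), k=1)] <= 0):
            raise ValueError("coincident feature points")

    @property
    def positions(self) -> np.ndarray:
        return np.stack([f.position for f in self.features])


@dataclass
class LigandConformer:
    id: str
    features: list[FeaturePoint]

    def __post_init__(self) -> None:
        if not self.features:
            raise ValueError(f"conformer {self.id}: no features")

    @property
    def positions(self) -> np.ndarray:
        return np.stack([f.position for f in self.features])


@dataclass
class MatchResult:
    ligand_id: str
    matched_pairs: tuple[tuple[int, int], ...]  # (model index, ligand index)
    alignment_rmsd: float  # Angstrom; inf when no valid mapping
    fit_score: float  # n_matched - rmsd / tolerance; 0 when failed
    passed: bool

    @property
    def n_matched(self) -> int:
        return len(self.matched_pairs)


# The nine trigger-site residues and the atom groups their feature
# points are placed on (centroid of the group).
def default_feature_spec() -> list[tuple[int, FeatureKind, str | tuple[str, ...]]]:
    return [
        (28, FeatureKind.hydrophobic, "sidechain"),
        (45, FeatureKind.hydrophobic, "sidechain"),
        (47, FeatureKind.hydrophobic, "sidechain"),
        (172, FeatureKind.hydrophobic, "sidechain"),
        (176, FeatureKind.aromatic, ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")),
        (109, FeatureKind.positive, ("NH1", "NH2", "CZ")),
        (48, FeatureKind.negative, ("OD1", "OD2", "CG")),
        (46, FeatureKind.donor, "N"),
        (164, FeatureKind.acceptor, ("OH",)),
    ]


def build_model(
    structure: Structure,
    feature_spec: Sequence[tuple[int, FeatureKind, str | tuple[str, ...]]] | None = None,
    tolerance: float = 2.0,
    rule: CompositionRule | None = None,
    model_index: int = 1,
) -> PharmacophoreModel:
    """Place one feature point per spec entry at its atom-set centroid."""
    if feature_spec is None:
        feature_spec = default_feature_spec()
    if not feature_spec:
        raise ValueError("empty feature spec")
    features = []
    for residue, kind, atom_rule in feature_spec:
        sel = AtomSelection(residue_number=residue, atom_name=atom_rule)
        pos = selection_centroid(structure, sel, model=model_index)
        features.append(FeaturePoint(kind=kind, position=pos, source_tag=f"res{residue}"))
    return PharmacophoreModel(
        features=features, tolerance=tolerance, rule=rule or CompositionRule()
    )


def _kind_compatible(
    model_kind: FeatureKind, ligand_kind: FeatureKind, allow_aromatic_as_hydrophobic: bool
) -> bool:
    if model_kind == ligand_kind:
        return True
    return (
        allow_aromatic_as_hydrophobic
        and model_kind == FeatureKind.hydrophobic
        and ligand_kind == FeatureKind.aromatic
    )


def enumerate_correspondences(
    model: PharmacophoreModel,
    conformer: LigandConformer,
    tolerance: float | None = None,
    min_size: int | None = None,
) -> list[tuple[tuple[int, int], ...]]:
    """All injective kind-compatible distance-consistent mappings.

    A mapping is a tuple of (model feature index, ligand feature index)
    pairs, sorted by model index.  Distance consistency: for every two
    pairs, |d_model - d_ligand| <= 2 * tolerance.  The bound is sound:
    after any rigid alignment placing both paired features within
    ``tolerance`` of their model partners, the inter-feature distances
    can disagree by at most 2 * tolerance (triangle inequality), so no
    alignable mapping is pruned.
    """
    tol = model.tolerance if tolerance is None else tolerance
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    size = model.rule.min_matched if min_size is None else min_size
    mpos = model.positions
    lpos = conformer.positions
    nm, nl = len(model.features), len(conformer.features)
    dmat_m = np.linalg.norm(mpos[:, None] - mpos[None, :], axis=-1)
    dmat_l = np.linalg.norm(lpos[:, None] - lpos[None, :], axis=-1)
    compat = [
        [
            _kind_compatible(
                model.features[i].kind,
                conformer.features[j].kind,
                model.allow_aromatic_as_hydrophobic,
            )
            for j in range(nl)
        ]
        for i in range(nm)
    ]
    results: list[tuple[tuple[int, int], ...]] = []
    pairs: list[tuple[int, int]] = []
    used = [False] * nl

    def extend(start: int) -> None:
        if len(pairs) >= size:
            results.append(tuple(pairs))
        # even a full extension cannot reach min size: prune
        if len(pairs) + (nm - start) < size:
            return
        for i in range(start, nm):
            for j in range(nl):
                if used[j] or not compat[i][j]:
                    continue
                if any(abs(dmat_m[i, pi] - dmat_l[j, pj]) > 2 * tol for pi, pj in pairs):
                    continue
                pairs.append((i, j))
                used[j] = True
                extend(i + 1)
                used[j] = False
                pairs.pop()

    extend(0)
    return results


def _evaluate_mapping(
    mapping: tuple[tuple[int, int], ...],
    mpos: np.ndarray,
    lpos: np.ndarray,
    tol: float,
) -> float | None:
    """RMSD of the best rigid fit, or None if any paired distance > tol."""
    mi = [p[0] for p in mapping]
    li = [p[1] for p in mapping]
    res = kabsch_superpose(mpos[mi], lpos[li])
    aligned = apply_transform(lpos[li], res)
    if np.any(np.linalg.norm(aligned - mpos[mi], axis=1) > tol + 1e-12):
        return None
    return res.rmsd


def match_conformer(
    model: PharmacophoreModel,
    conformer: LigandConformer,
    tolerance: float | None = None,
    rule: CompositionRule | None = None,
) -> MatchResult:
    """Best valid rigid match of a conformer onto the model.

    Over all composition-valid candidate correspondences (every
    post-alignment paired distance within tolerance) the mapping
    maximising ``fit_score = n_matched - rmsd / tolerance`` wins; since
    rmsd/tolerance <= 1 for a valid mapping this prefers more matched
    points, then lower alignment RMSD, then the lexicographically
    smallest mapping.
    """
    tol = model.tolerance if tolerance is None else tolerance
    r = rule or model.rule
    mpos = model.positions
    lpos = conformer.positions
    best: tuple[int, float, tuple[tuple[int, int], ...]] | None = None
    for mapping in enumerate_correspondences(model, conformer, tol, r.min_matched):
        kinds = [model.features[i].kind for i, _ in mapping]
        if not r.satisfied(kinds):
            continue
        rmsd = _evaluate_mapping(mapping, mpos, lpos, tol)
        if rmsd is None:
            continue
        key = (-len(mapping), rmsd, mapping)
        if best is None or key < best:
            best = key
    if best is None:
        return MatchResult(conformer.id, (), float("inf"), 0.0, False)
    _, rmsd, mapping = best
    score = len(mapping) - rmsd / tol
    return MatchResult(conformer.id, mapping, rmsd, score, True)


def screen_library(
    model: PharmacophoreModel,
    conformers: Iterable[LigandConformer],
    tolerance: float | None = None,
    rule: CompositionRule | None = None,
    top_k: int = 1000,
) -> pd.DataFrame:
    """Rank a conformer library; at most ``top_k`` rows.

    Sort order: passed (descending), fit_score (descending), ligand id
    (ascending) — deterministic for fixed inputs.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    results = [match_conformer(model, c, tolerance, rule) for c in conformers]
    results.sort(key=lambda r: (not r.passed, -r.fit_score, r.ligand_id))
    rows = [
        {
            "ligand_id": r.ligand_id,
            "passed": r.passed,
            "n_matched": r.n_matched,
            "alignment_rmsd": r.alignment_rmsd,
            "fit_score": r.fit_score,
            "matched_pairs": ";".join(f"{i}-{j}" for i, j in r.matched_pairs),
        }
        for r in results[:top_k]
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "ligand_id",
            "passed",
            "n_matched",
            "alignment_rmsd",
            "fit_score",
            "matched_pairs",
        ],
    )


# ---------------------------------------------------------------------------
# Serialisation: conformer libraries as TSV, models as YAML.

def load_library_tsv(path) -> list[LigandConformer]:
    df = pd.read_csv(path, sep="\t")
    required = {"ligand_id", "feature_kind", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise ValueError(f"library TSV needs columns {sorted(required)}")
    conformers = []
    for lid, grp in df.groupby("ligand_id", sort=True):
        feats = [
            FeaturePoint(FeatureKind(row.feature_kind), np.array([row.x, row.y, row.z]))
            for row in grp.itertuples()
        ]
        conformers.append(LigandConformer(str(lid), feats))
    return conformers


def save_library_tsv(conformers: Sequence[LigandConformer], path) -> None:
    rows = [
        {
            "ligand_id": c.id,
            "feature_kind": f.kind.value,
            "x": f.position[0],
            "y": f.position[1],
            "z": f.position[2],
        }
        for c in conformers
        for f in c.features
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def save_model_yaml(model: PharmacophoreModel, path) -> None:
    doc = {
        "tolerance": model.tolerance,
        "allow_aromatic_as_hydrophobic": model.allow_aromatic_as_hydrophobic,
        "rule": {
            "min_matched": model.rule.min_matched,
            "min_hydrophobic": model.rule.min_hydrophobic,
            "min_aromatic": model.rule.min_aromatic,
            "min_polar_or_charged": model.rule.min_polar_or_charged,
            "polar_or_charged_from_size": model.rule.polar_or_charged_from_size,
        },
        "features": [
            {
                "kind": f.kind.value,
                "position": [float(x) for x in f.position],
                "source_tag": f.source_tag,
            }
            for f in model.features
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_model_yaml(path) -> PharmacophoreModel:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    features = [
        FeaturePoint(FeatureKind(f["kind"]), np.array(f["position"]), f.get("source_tag", ""))
        for f in doc["features"]
    ]
    return PharmacophoreModel(
        features=features,
        tolerance=float(doc.get("tolerance", 2.0)),
        rule=CompositionRule(**doc.get("rule", {})),
        allow_aromatic_as_hydrophobic=bool(doc.get("allow_aromatic_as_hydrophobic", False)),
    )
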