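"""HSQC chemical-shift-perturbation analysis.

Per-residue CSP between a reference (apo) and a ligand-bound peak list:

    CSP = overall_scale * sqrt(ddH^2 + (nitrogen_scale * ddN)^2)

with ``nitrogen_scale = 1/5`` and ``overall_scale = 1/2`` by default,
i.e. the literal reading sqrt(ddH^2 + (ddN/5)^2) / 2 in ppm.  The common
alternative convention sqrt((ddH^2 + (ddN/5)^2) / 2) is one parameter
change away (overall_scale = 1/sqrt(2) applied the same way does not
reproduce it exactly; use ``rms_convention=True`` instead).

Significance is classified against the mean CSP across assigned
residues plus 0.5 or 1 sample standard deviations.  Residues absent
from either list (prolines, overlapped or missing peaks) carry no CSP
and are excluded from the mean/SD.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "PeakList",
    "CSPClass",
    "CSPRecord",
    "RegionTable",
    "compute_csp",
    "classify_csp",
    "map_to_regions",
    "csp_records_to_frame",
]


class CSPClass(str, enum.Enum):
    absent = "absent"
    below = "below"
    significant = "significant"
    highly_significant = "highly_significant"


@dataclass
class PeakList:
    """residue -> (delta 1H ppm, delta 15N ppm)."""

    entries: dict[int, tuple[float, float]]
    label: str = ""

    def __post_init__(self) -> None:
        for res, (h, n) in self.entries.items():
            if not (np.isfinite(h) and np.isfinite(n)):
                raise ValueError(f"residue {res}: non-finite shift")

    @classmethod
    def from_tsv(cls, path, label: str = "") -> "PeakList":
        df = pd.read_csv(path, sep="\t")
        entries = {
            int(r.residue): (float(r.delta_H_ppm), float(r.delta_N_ppm))
            for r in df.itertuples()
        }
        return cls(entries, label or str(path))

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            [
                {"residue": res, "delta_H_ppm": h, "delta_N_ppm": n}
                for res, (h, n) in sorted(self.entries.items())
            ]
        ).to_csv(path, sep="\t", index=False)


@dataclass
class CSPRecord:
    residue_number: int
    delta_dH: float  # ppm
    delta_dN: float  # ppm
    csp: float  # ppm; NaN when absent
    csp_class: CSPClass = CSPClass.below


def compute_csp(
    ref: PeakList,
    bound: PeakList,
    nitrogen_scale: float = 1 / 5,
    overall_scale: float = 1 / 2,
    rms_convention: bool = False,
) -> list[CSPRecord]:
    """Weighted-average CSP for every residue in either peak list.

    Residues present in only one list are emitted with class ``absent``
    and an undefined (NaN) CSP.  ``rms_convention=True`` switches to
    sqrt((ddH^2 + (s*ddN)^2) / 2) in place of the default
    overall_scale * sqrt(...).
    """
    if not ref.entries or not bound.entries:
        raise ValueError("empty peak list")
    common = set(ref.entries) & set(bound.entries)
    if not common:
        raise ValueError("peak lists share no residues; nothing to compare")
    records = []
    for res in sorted(set(ref.entries) | set(bound.entries)):
        if res not in common:
            records.append(CSPRecord(res, np.nan, np.nan, np.nan, CSPClass.absent))
            continue
        dh = bound.entries[res][0] - ref.entries[res][0]
        dn = bound.entries[res][1] - ref.entries[res][1]
        ss = dh**2 + (nitrogen_scale * dn) ** 2
        csp = float(np.sqrt(ss / 2)) if rms_convention else float(overall_scale * np.sqrt(ss))
        records.append(CSPRecord(res, dh, dn, csp))
    return records


def classify_csp(
    records: list[CSPRecord],
) -> tuple[list[CSPRecord], dict[str, float]]:
    """Fill significance classes in place; returns (records, thresholds).

    With m the mean and s the sample SD (ddof=1) of the CSPs over
    non-absent residues: CSP > m + s is highly significant, m + 0.5 s <
    CSP <= m + s is significant, the rest fall below threshold.
    """
    values = np.array([r.csp for r in records if r.csp_class != CSPClass.absent])
    if values.size < 2:
        raise ValueError("need at least 2 assigned residues to estimate the SD")
    m = float(values.mean())
    s = float(values.std(ddof=1))
    for r in records:
        if r.csp_class == CSPClass.absent:
            continue
        if r.csp > m + s:
            r.csp_class = CSPClass.highly_significant
        elif r.csp > m + 0.5 * s:
            r.csp_class = CSPClass.significant
        else:
            r.csp_class = CSPClass.below
    thresholds = {"mean": m, "sd": s, "significant": m + 0.5 * s, "highly_significant": m + s}
    return records, thresholds


@dataclass
class RegionTable:
    """Structural-region labels (helices, loops) -> inclusive residue range."""

    regions: dict[str, tuple[int, int]]

    def __post_init__(self) -> None:
        spans = sorted(self.regions.items(), key=lambda kv: kv[1][0])
        for (la, (_, a1)), (lb, (b0, _)) in zip(spans, spans[1:]):
            if b0 <= a1:
                raise ValueError(f"regions {la!r} and {lb!r} overlap")
        for label, (lo, hi) in self.regions.items():
            if lo > hi:
                raise ValueError(f"region {label!r}: empty range")

    def assign(self, residue: int) -> str:
        for label, (lo, hi) in self.regions.items():
            if lo <= residue <= hi:
                return label
        return "unassigned"

    @classmethod
    def from_yaml(cls, path) -> "RegionTable":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls({str(k): (int(v[0]), int(v[1])) for k, v in doc.items()})


def map_to_regions(
    records: list[CSPRecord], regions: RegionTable
) -> dict[str, dict[str, object]]:
    """Per-region significance summary.

    Every residue lands in exactly one region (or "unassigned").  Counts
    cover the two significance tiers plus the residue lists behind them.
    """
    summary: dict[str, dict[str, object]] = {}
    for r in records:
        label = regions.assign(r.residue_number)
        bucket = summary.setdefault(
            label,
            {"n_residues": 0, "significant": 0, "highly_significant": 0,
             "significant_residues": [], "highly_significant_residues": []},
        )
        bucket["n_residues"] += 1
        if r.csp_class == CSPClass.significant:
            bucket["significant"] += 1
            bucket["significant_residues"].append(r.residue_number)
        elif r.csp_class == CSPClass.highly_significant:
            bucket["highly_significant"] += 1
            bucket["highly_significant_residues"].append(r.residue_number)
    return summary


def csp_records_to_frame(records: list[CSPRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "residue": r.residue_number,
                "delta_dH_ppm": r.delta_dH,
                "delta_dN_ppm": r.delta_dN,
                "csp_ppm": r.csp,
                "class": r.csp_class.value,
            }
            for r in records
        ]
    )
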