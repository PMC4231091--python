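"""Broadening classification, +/-Ca2+ distance profiles and summaries.

The qualitative readout of a PRE experiment bins each residue's intensity
ratio: strong broadening (ratio below ~0.4) marks residues close to the
label, near-unity ratios mark residues beyond its reach.  The
quantitative readout pairs per-residue distances measured with and
without calcium, yielding a displacement profile whose region averages
summarize which parts of the observed protein the label moved toward or
away from.  Per-residue values can also be exported onto a structure
(B-factor recoding plus a Chimera-style attribute file) for visual
mapping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import pandas as pd

from .core import DistanceEstimate, DistanceWindow
from .structure import RegionDef, ReferenceDistanceSet, StructureHandle, region_average

__all__ = [
    "BroadeningClass",
    "ClassThresholds",
    "ResidueProfile",
    "classify_ratio",
    "delta_distances",
    "summarize_regions",
    "export_structure_coloring",
]


class BroadeningClass(str, Enum):
    strong = "strong"
    moderate = "moderate"
    weak = "weak"
    unaffected = "unaffected"
    unknown = "unknown"


@dataclass(frozen=True)
class ClassThresholds:
    """Ratio cut points for the broadening bins.

    ``strong_max``/``moderate_max`` are the published 0.4 / 0.5 cuts;
    ``unaffected_min`` operationalizes "ratio ~ 1" (no number is printed
    for it, so it is configurable).  Boundary values go to the stronger
    class.
    """

    strong_max: float = 0.4
    moderate_max: float = 0.5
    unaffected_min: float = 0.85

    def __post_init__(self) -> None:
        if not 0 < self.strong_max <= self.moderate_max <= self.unaffected_min:
            raise ValueError("thresholds must be ordered: "
                             "0 < strong_max <= moderate_max <= unaffected_min")


@dataclass(frozen=True)
class ResidueProfile:
    """Paired +/-Ca2+ distances for one residue under one label site.

    ``delta_r`` is stored as ``r(-Ca) - r(+Ca)`` — positive means the
    residue moved *away* from the label upon calcium removal — and is
    defined only when both states are quantifiable.  One-sided profiles
    (one state censored) keep the available distance and a None delta.
    """

    residue_id: int
    r_plus: float | None
    r_minus: float | None
    window_plus: DistanceWindow | None
    window_minus: DistanceWindow | None
    delta_r: float | None
    direction: str | None   # "away" | "toward" | None


def classify_ratio(ratio: float,
                   thresholds: ClassThresholds = ClassThresholds()
                   ) -> BroadeningClass:
    """Deterministic bin assignment for one intensity ratio.

    Monotone by construction: a lower ratio never yields a weaker class.
    NaN (e.g. a residue with no diamagnetic reference) maps to
    ``unknown``.
    """
    if math.isnan(ratio):
        return BroadeningClass.unknown
    if ratio < 0:
        raise ValueError("ratio must be non-negative")
    if ratio <= thresholds.strong_max:
        return BroadeningClass.strong
    if ratio <= thresholds.moderate_max:
        return BroadeningClass.moderate
    if ratio < thresholds.unaffected_min:
        return BroadeningClass.weak
    return BroadeningClass.unaffected


def delta_distances(plus: Sequence[DistanceEstimate],
                    minus: Sequence[DistanceEstimate]
                    ) -> list[ResidueProfile]:
    """Pair +Ca2+ and -Ca2+ distance estimates residue by residue.

    Residues quantifiable in both states get ``delta_r`` and a direction
    tag; residues quantifiable in only one state are reported one-sided.
    Disjoint residue sets produce an empty list (callers may warn).
    """
    plus_map = {e.residue_id: e for e in plus}
    minus_map = {e.residue_id: e for e in minus}
    profiles: list[ResidueProfile] = []
    for rid in sorted(set(plus_map) | set(minus_map)):
        p = plus_map.get(rid)
        m = minus_map.get(rid)
        r_p = p.r if p is not None and math.isfinite(p.r) else None
        r_m = m.r if m is not None and math.isfinite(m.r) else None
        quant_p = p is not None and p.window is DistanceWindow.quantifiable
        quant_m = m is not None and m.window is DistanceWindow.quantifiable
        if quant_p and quant_m:
            delta = r_m - r_p
            direction = "away" if delta > 0 else ("toward" if delta < 0 else None)
        else:
            delta = None
            direction = None
        profiles.append(ResidueProfile(
            residue_id=rid,
            r_plus=r_p, r_minus=r_m,
            window_plus=p.window if p is not None else None,
            window_minus=m.window if m is not None else None,
            delta_r=delta, direction=direction))
    return profiles


def summarize_regions(profiles: Sequence[ResidueProfile],
                      regions: Sequence[RegionDef],
                      reference: ReferenceDistanceSet | None = None,
                      reference_sites: Sequence[int] | None = None,
                      table_sign: bool = False) -> pd.DataFrame:
    """Region-averaged summary of a +/-Ca2+ comparison.

    One row per region with the mean quantifiable distance in each state,
    the mean displacement over residues quantifiable in both, and (when a
    crystal reference is given) the mean reference distance.  With
    ``table_sign=True`` the displacement column is rendered as
    ``r(+Ca) - r(-Ca)`` — the sign convention used in published summary
    tables — instead of the stored ``r(-Ca) - r(+Ca)``.

    Invariant to residue ordering and to splitting the input into
    batches (it is a plain mean over the region members).
    """
    rows = []
    for region in regions:
        members = [p for p in profiles if p.residue_id in region]
        plus_vals = [p.r_plus for p in members
                     if p.window_plus is DistanceWindow.quantifiable]
        minus_vals = [p.r_minus for p in members
                      if p.window_minus is DistanceWindow.quantifiable]
        deltas = [p.delta_r for p in members if p.delta_r is not None]
        ref_mean = None
        if reference is not None:
            try:
                ref_mean = region_average(reference, region,
                                          sites=reference_sites)
            except ValueError:
                ref_mean = None
        delta_mean = sum(deltas) / len(deltas) if deltas else None
        if delta_mean is not None and table_sign:
            delta_mean = -delta_mean
        rows.append({
            "region": region.name,
            "start": region.start,
            "end": region.end,
            "n_pairs": len(deltas),
            "r_plusCa_mean": (sum(plus_vals) / len(plus_vals)
                              if plus_vals else None),
            "r_minusCa_mean": (sum(minus_vals) / len(minus_vals)
                               if minus_vals else None),
            "delta_mean": delta_mean,
            "reference_mean": ref_mean,
        })
    return pd.DataFrame(rows)


_UNMAPPED_SENTINEL = 999.0


def export_structure_coloring(values: Mapping[int, float],
                              handle: StructureHandle,
                              pdb_out: str | Path,
                              attr_out: str | Path,
                              mode: str = "ratio",
                              attribute_name: str | None = None) -> None:
    """Write per-residue values onto a structure for molecular graphics.

    Two artifacts: (a) a copy of the structure whose B-factor column on
    the observed chain carries the value scaled to [0, 100] (intensity
    ratios are multiplied by 100; displacement values are min-max scaled),
    residues without a value flagged 999; (b) a UCSF-Chimera ``defattr``
    attribute file carrying the raw values.
    """
    if mode not in ("ratio", "delta_r"):
        raise ValueError(f"unknown coloring mode {mode!r}")
    finite = {rid: v for rid, v in values.items() if math.isfinite(v)}
    if mode == "ratio":
        scaled = {rid: min(max(v * 100.0, 0.0), 100.0)
                  for rid, v in finite.items()}
    else:
        if finite:
            lo = min(finite.values())
            hi = max(finite.values())
            span = (hi - lo) or 1.0
            scaled = {rid: (v - lo) / span * 100.0
                      for rid, v in finite.items()}
        else:
            scaled = {}

    st = handle.structure.clone()
    observed = handle.chain_map["observed"]
    for model in st:
        for chain in model:
            if chain.name != observed:
                continue
            for res in chain:
                b = scaled.get(res.seqid.num, _UNMAPPED_SENTINEL)
                for atom in res:
                    atom.b_iso = b
    st.setup_entities()
    doc_path = Path(pdb_out)
    st.write_pdb(str(doc_path))

    name = attribute_name or ("preRatio" if mode == "ratio" else "preDeltaR")
    lines = [f"attribute: {name}",
             "match mode: 1-to-1",
             "recipient: residues"]
    for rid in sorted(finite):
        lines.append(f"\t:{rid}.{observed}\t{finite[rid]:.4f}")
    Path(attr_out).write_text("\n".join(lines) + "\n")
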