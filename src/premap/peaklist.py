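"""Assigned 2D 1H-15N peak lists and paramagnetic/diamagnetic pairing.

Reads the whitespace-separated text dialect exported by Sparky-style
assignment programs::

    # comment
         Assignment     w1      w2   Data Height   lw1 (hz)
           G42N-H    110.20   8.31      1.5e6        12.4

Assignments are parsed as one-letter residue code + author residue number
+ atom pair (``N-H`` or ``N-HN``).  Peak heights stand in for intensities;
the optional linewidth column is the proton full width at half height.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "Peak",
    "PeakList",
    "RatioRecord",
    "SpinState",
    "CaCondition",
    "RatioFlag",
    "read_peaklist",
    "write_peaklist",
    "pair_and_ratio",
    "write_ratio_table",
]

_AA3 = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}

# e.g. "G42N-H", "Q50N-HN"; group 1 = residue code, 2 = author number
_ASSIGNMENT_RE = re.compile(r"^([A-Za-z])(\d+)N-HN?$")


class SpinState(str, Enum):
    paramagnetic = "paramagnetic"
    diamagnetic = "diamagnetic"


class CaCondition(str, Enum):
    plusCa = "plusCa"
    minusCa = "minusCa"


class RatioFlag(str, Enum):
    ok = "ok"
    undetected_para = "undetected_para"
    missing_dia = "missing_dia"
    unassigned = "unassigned"


@dataclass(frozen=True)
class Peak:
    """One assigned amide cross-peak."""

    residue_id: int
    residue_name: str
    shift_n: float   # ppm
    shift_h: float   # ppm
    height: float    # arbitrary intensity units
    linewidth_h: float | None = None  # Hz, full width at half height

    def __post_init__(self) -> None:
        if self.height <= 0:
            raise ValueError(
                f"residue {self.residue_id}: peak height must be positive")
        if self.linewidth_h is not None and self.linewidth_h <= 0:
            raise ValueError(
                f"residue {self.residue_id}: linewidth must be positive")


@dataclass(frozen=True)
class PeakList:
    """One spectrum's assigned peaks plus its experimental metadata."""

    peaks: tuple[Peak, ...]
    state: SpinState
    condition: CaCondition
    label_site: int
    spectrometer_mhz: float = 600.0

    def __post_init__(self) -> None:
        seen: dict[int, Peak] = {}
        for p in self.peaks:
            if p.residue_id in seen:
                raise ValueError(
                    f"duplicate peak for residue {p.residue_name}"
                    f"{p.residue_id}")
            seen[p.residue_id] = p

    def by_residue(self) -> dict[int, Peak]:
        return {p.residue_id: p for p in self.peaks}

    @property
    def residue_ids(self) -> list[int]:
        return sorted(p.residue_id for p in self.peaks)


@dataclass(frozen=True)
class RatioRecord:
    """Per-residue I_para/I_dia with uncertainty and status flag."""

    residue_id: int
    ratio: float
    ratio_sigma: float
    flag: RatioFlag = RatioFlag.ok

    def __post_init__(self) -> None:
        if self.ratio < 0:
            raise ValueError("ratio must be non-negative")


def _parse_assignment(token: str, lineno: int) -> tuple[int, str]:
    m = _ASSIGNMENT_RE.match(token)
    if not m:
        raise ValueError(
            f"line {lineno}: cannot parse assignment {token!r} "
            "(expected e.g. 'G42N-H' or 'G42N-HN')")
    code, number = m.group(1).upper(), int(m.group(2))
    if code not in _AA3:
        raise ValueError(
            f"line {lineno}: unknown residue code {code!r} in {token!r}")
    return number, _AA3[code]


def read_peaklist(path: str | Path, *, state: SpinState | str,
                  condition: CaCondition | str, label_site: int,
                  spectrometer_mhz: float = 600.0) -> PeakList:
    """Read and validate one Sparky-dialect peak list.

    Each data line carries assignment, 15N shift, 1H shift, height and an
    optional linewidth.  Lines starting with ``#`` and a leading
    ``Assignment`` header are ignored.  Malformed lines and duplicate
    assignments raise with the offending line number or residue.
    """
    path = Path(path)
    peaks: list[Peak] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if fields[0].lower() == "assignment":
                continue
            if fields[0].startswith("?"):
                continue  # unassigned peak: unusable for per-residue ratios
            if len(fields) < 4:
                raise ValueError(
                    f"{path.name} line {lineno}: expected at least 4 "
                    f"columns, got {len(fields)}")
            residue_id, residue_name = _parse_assignment(fields[0], lineno)
            try:
                shift_n, shift_h, height = (float(fields[1]),
                                            float(fields[2]),
                                            float(fields[3]))
            except ValueError as exc:
                raise ValueError(
                    f"{path.name} line {lineno}: non-numeric value "
                    f"({exc})") from None
            linewidth = float(fields[4]) if len(fields) > 4 else None
            peaks.append(Peak(residue_id, residue_name, shift_n, shift_h,
                              height, linewidth))
    if not peaks:
        raise ValueError(f"{path.name}: no peaks")
    return PeakList(tuple(peaks), SpinState(state), CaCondition(condition),
                    label_site, spectrometer_mhz)


def write_peaklist(peaklist: PeakList, path: str | Path,
                   header: Iterable[str] = ()) -> None:
    """Write a peak list in the same dialect :func:`read_peaklist` reads.

    Heights and shifts round-trip at full precision (``repr`` formatting).
    Extra header lines are emitted as ``#`` comments.
    """
    path = Path(path)
    lines = [f"# {h}" for h in header]
    lines.append(f"# state={peaklist.state.value} "
                 f"condition={peaklist.condition.value} "
                 f"label_site={peaklist.label_site} "
                 f"spectrometer_mhz={peaklist.spectrometer_mhz}")
    lines.append("# Assignment  w1(15N,ppm)  w2(1H,ppm)  height  lw(1H,Hz)")
    one_letter = {v: k for k, v in _AA3.items()}
    for p in sorted(peaklist.peaks, key=lambda q: q.residue_id):
        tag = f"{one_letter[p.residue_name]}{p.residue_id}N-H"
        cols = [tag, repr(float(p.shift_n)), repr(float(p.shift_h)),
                repr(float(p.height))]
        if p.linewidth_h is not None:
            cols.append(repr(float(p.linewidth_h)))
        lines.append("  ".join(cols))
    path.write_text("\n".join(lines) + "\n")


def pair_and_ratio(para: PeakList, dia: PeakList, floor: float = 0.05,
                   sigma_frac: float = 0.05) -> list[RatioRecord]:
    """Pair spectra and compute per-residue I_para/I_dia.

    The diamagnetic list defines the residue universe.  A residue present
    in both lists yields ``ratio = height_para / height_dia``; one absent
    from the paramagnetic list is broadened beyond detection and is
    assigned the configured floor ratio with flag ``undetected_para``.
    Residues only in the paramagnetic list are flagged ``missing_dia``
    (excluded from distance analysis downstream).  Ratios above 1
    (possible with noise) are kept as-is; clipping happens at the
    rate-conversion step so the raw data stay auditable.
    """
    if para.state is not SpinState.paramagnetic:
        raise ValueError(f"first argument must be paramagnetic, "
                         f"got state={para.state.value}")
    if dia.state is not SpinState.diamagnetic:
        raise ValueError(f"second argument must be diamagnetic, "
                         f"got state={dia.state.value}")
    if para.condition is not dia.condition or para.label_site != dia.label_site:
        raise ValueError(
            "paramagnetic/diamagnetic lists disagree on condition or "
            f"label site: ({para.condition.value}, {para.label_site}) vs "
            f"({dia.condition.value}, {dia.label_site})")
    para_peaks = para.by_residue()
    records: list[RatioRecord] = []
    for rid, dpeak in sorted(dia.by_residue().items()):
        if rid in para_peaks:
            ratio = para_peaks[rid].height / dpeak.height
            records.append(RatioRecord(rid, ratio, sigma_frac * ratio,
                                       RatioFlag.ok))
        else:
            records.append(RatioRecord(rid, floor, 0.0,
                                       RatioFlag.undetected_para))
    dia_ids = set(dia.by_residue())
    for rid in sorted(set(para_peaks) - dia_ids):
        records.append(RatioRecord(rid, float("nan"), float("nan"),
                                   RatioFlag.missing_dia))
    return records


def write_ratio_table(records: Sequence[RatioRecord],
                      path: str | Path, header: Iterable[str] = ()) -> None:
    """Write ratio records as TSV (residue_id, ratio, sigma, flag)."""
    path = Path(path)
    lines = [f"# {h}" for h in header]
    lines.append("residue_id\tratio\tratio_sigma\tflag")
    for rec in records:
        lines.append(f"{rec.residue_id}\t{rec.ratio:.6g}\t"
                     f"{rec.ratio_sigma:.6g}\t{rec.flag.value}")
    path.write_text("\n".join(lines) + "\n")
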