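"""Mutant-panel analytics: fold changes, hotspot calling, assay concordance.

Works on tables of phosphopeptide variants measured in two orthogonal
affinity assays (a direct SPR KD and a displacement NMR Ki).  The packaged
fixture ``table2_fixture.csv`` holds the published 13-peptide GHR_pY595 and
10-peptide EpoR_pY426 panels (wild type, V(-3) substitutions and alanine
scans) that the analytics reproduce.

Conventions
-----------
* Sequences carry ``pY`` marking the single phosphotyrosine anchor.
* Position labels are relative to pY: ``pY(-3)`` is an alanine substitution
  three residues N-terminal of the anchor; ``V(-3)R`` a non-alanine
  substitution at the same offset; ``WT`` the wild type.
* Fold changes are mutant/wild-type ratios per assay within a panel; a
  fold change > 1 means weakened binding.
* Concordance between the two assays is Pearson correlation of
  log10-transformed affinities pooled across panels (affinities are treated
  as log-normal).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

__all__ = [
    "PeptideRecord",
    "PanelTable",
    "ConcordanceReport",
    "HotspotReport",
    "load_panel",
    "packaged_panel_path",
    "assay_concordance",
    "fold_changes",
    "call_hotspots",
]

_POSITION_RE = re.compile(r"^(?:pY|[A-Z])\(([+-]?\d+)\)[A-Z]?$")

HotspotRule = Literal["geometric_mean", "either", "both"]


def parse_position_label(label: str) -> int | None:
    """Offset relative to pY, or None for the wild type.

    Accepts 'WT', 'pY(-3)', 'pY(+4)', 'V(-3)R', 'V(-3)Y' style labels.
    Unicode minus signs are normalised to ASCII.
    """
    label = label.strip().replace("−", "-")
    if label.upper() == "WT":
        return None
    m = _POSITION_RE.match(label)
    if m is None:
        raise ValueError(f"cannot parse position label {label!r}")
    return int(m.group(1))


@dataclass(frozen=True)
class PeptideRecord:
    peptide_id: str
    panel: str
    sequence: str
    position_label: str
    kd_spr: float
    kd_spr_sem: float
    ki_nmr: float
    ki_nmr_sem: float

    def __post_init__(self) -> None:
        if self.sequence.count("pY") != 1:
            raise ValueError(
                f"{self.peptide_id}: sequence must contain exactly one pY, "
                f"got {self.sequence!r}"
            )
        parse_position_label(self.position_label)  # raises if malformed

    @property
    def offset(self) -> int | None:
        return parse_position_label(self.position_label)

    @property
    def is_wild_type(self) -> bool:
        return self.offset is None

    @property
    def is_alanine_scan(self) -> bool:
        """True for plain alanine substitutions labelled pY(+/-n)."""
        return self.position_label.strip().replace("−", "-").startswith("pY(")


@dataclass(frozen=True)
class PanelTable:
    records: tuple[PeptideRecord, ...]

    def __post_init__(self) -> None:
        ids = [r.peptide_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = {i for i in ids if ids.count(i) > 1}
            raise ValueError(f"duplicate peptide_ids: {sorted(dupes)}")
        for panel in self.panels:
            wt = [r for r in self.records if r.panel == panel and r.is_wild_type]
            if len(wt) != 1:
                raise ValueError(
                    f"panel {panel!r} must contain exactly one wild type, "
                    f"found {len(wt)}"
                )

    @property
    def panels(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.panel, None)
        return tuple(seen)

    def wild_type(self, panel: str) -> PeptideRecord:
        return next(r for r in self.records if r.panel == panel and r.is_wild_type)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "peptide_id": [r.peptide_id for r in self.records],
                "panel": [r.panel for r in self.records],
                "sequence": [r.sequence for r in self.records],
                "position_label": [r.position_label for r in self.records],
                "kd_spr_uM": [r.kd_spr for r in self.records],
                "kd_spr_sem": [r.kd_spr_sem for r in self.records],
                "ki_nmr_uM": [r.ki_nmr for r in self.records],
                "ki_nmr_sem": [r.ki_nmr_sem for r in self.records],
            }
        )

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class ConcordanceReport:
    n: int
    r: float
    transform: str

    @property
    def r_squared(self) -> float:
        return self.r * self.r

    def summary(self) -> str:
        return (
            f"cross-assay concordance: n={self.n}, r={self.r:.3f}, "
            f"R^2={self.r_squared:.2f} ({self.transform} scale)"
        )


@dataclass(frozen=True)
class HotspotReport:
    """Per-position fold changes and the called hotspot set, per panel."""

    table: pd.DataFrame  # columns: panel, position_label, offset, fc_spr, fc_nmr, score, hotspot
    rule: str
    threshold: float

    def hotspots(self, panel: str) -> set[str]:
        mask = (self.table["panel"] == panel) & self.table["hotspot"]
        return set(self.table.loc[mask, "position_label"])


def packaged_panel_path() -> Path:
    """Filesystem path of the packaged published-panel fixture."""
    return Path(str(resources.files("sh2bind").joinpath("data/table2_fixture.csv")))


def load_panel(path: str | Path | None = None) -> PanelTable:
    """Load and validate a panel CSV; defaults to the packaged fixture.

    Required columns: peptide_id, panel, sequence, position_label,
    kd_spr_uM, kd_spr_sem, ki_nmr_uM, ki_nmr_sem.
    """
    if path is None:
        path = packaged_panel_path()
    df = pd.read_csv(path)
    required = {"peptide_id", "panel", "sequence", "position_label",
                "kd_spr_uM", "kd_spr_sem", "ki_nmr_uM", "ki_nmr_sem"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"panel CSV missing columns {sorted(missing)}")
    errors: list[str] = []
    records: list[PeptideRecord] = []
    for _, row in df.iterrows():
        try:
            records.append(
                PeptideRecord(
                    peptide_id=str(row["peptide_id"]),
                    panel=str(row["panel"]),
                    sequence=str(row["sequence"]),
                    position_label=str(row["position_label"]),
                    kd_spr=float(row["kd_spr_uM"]),
                    kd_spr_sem=float(row["kd_spr_sem"]),
                    ki_nmr=float(row["ki_nmr_uM"]),
                    ki_nmr_sem=float(row["ki_nmr_sem"]),
                )
            )
        except (ValueError, TypeError) as exc:
            errors.append(f"row {row['peptide_id']!r}: {exc}")
    if errors:
        raise ValueError("malformed panel rows:\n" + "\n".join(errors))
    return PanelTable(records=tuple(records))


def save_panel(table: PanelTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, index=False)


def assay_concordance(
    table: PanelTable,
    transform: Literal["log10", "none"] = "log10",
) -> ConcordanceReport:
    """Pearson correlation between the two assays' affinities, pooled.

    Affinities span orders of magnitude and are treated as log-normal, so the
    default correlates log10(KD) with log10(Ki) across all records of all
    panels.
    """
    kd = np.array([r.kd_spr for r in table.records], dtype=float)
    ki = np.array([r.ki_nmr for r in table.records], dtype=float)
    mask = np.isfinite(kd) & np.isfinite(ki)
    kd, ki = kd[mask], ki[mask]
    if kd.size < 3:
        raise ValueError("need at least 3 complete (KD, Ki) pairs")
    if transform == "log10":
        kd, ki = np.log10(kd), np.log10(ki)
    if np.std(kd) == 0 or np.std(ki) == 0:
        raise ValueError("zero variance in an assay column; correlation undefined")
    r = float(np.corrcoef(kd, ki)[0, 1])
    return ConcordanceReport(n=int(kd.size), r=r, transform=transform)


def fold_changes(table: PanelTable) -> pd.DataFrame:
    """Mutant/wild-type affinity ratios per assay, within each panel.

    Returns one row per record with columns fc_spr and fc_nmr; the wild type
    has fold change 1 in both assays by construction.  Missing affinities
    yield NaN fold changes.
    """
    rows = []
    for panel in table.panels:
        wt = table.wild_type(panel)
        for r in (x for x in table.records if x.panel == panel):
            rows.append({
                "peptide_id": r.peptide_id,
                "panel": panel,
                "position_label": r.position_label,
                "offset": r.offset,
                "alanine_scan": r.is_alanine_scan,
                "fc_spr": r.kd_spr / wt.kd_spr if math.isfinite(r.kd_spr) else float("nan"),
                "fc_nmr": r.ki_nmr / wt.ki_nmr if math.isfinite(r.ki_nmr) else float("nan"),
            })
    return pd.DataFrame(rows)


def call_hotspots(
    fc: pd.DataFrame,
    rule: HotspotRule = "geometric_mean",
    threshold: float = 2.0,
) -> HotspotReport:
    """Call energetic hotspot positions from alanine-scan fold changes.

    Only alanine-scan rows (labels pY(+/-n)) are scanned; targeted non-Ala
    substitutions probe chemistry, not the alanine-deletion energetics.  The
    default rule scores each position by the geometric mean of the two
    assays' fold changes and calls a hotspot at score >= 2 (an "at least
    two-fold weakened binding" consensus).  ``either`` / ``both`` require one
    / both single-assay fold changes to clear the threshold.
    """
    scan = fc[fc["alanine_scan"] & fc["offset"].notna()].copy()
    scan["score"] = np.sqrt(scan["fc_spr"] * scan["fc_nmr"])
    if rule == "geometric_mean":
        scan["hotspot"] = scan["score"] >= threshold
    elif rule == "either":
        scan["hotspot"] = (scan["fc_spr"] >= threshold) | (scan["fc_nmr"] >= threshold)
    elif rule == "both":
        scan["hotspot"] = (scan["fc_spr"] >= threshold) & (scan["fc_nmr"] >= threshold)
    else:
        raise ValueError(f"unknown hotspot rule {rule!r}")
    cols = ["panel", "position_label", "offset", "fc_spr", "fc_nmr", "score", "hotspot"]
    return HotspotReport(table=scan[cols].reset_index(drop=True),
                         rule=rule, threshold=threshold)
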