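"""Experimental design of the grated-cheese sensing study.

The study crosses two ripening stages ("seasoning": 12 vs 24 months) with two
rind working processes (washed rind, WR; scraped rind, SR) and eleven nominal
rind percentages, grouped into three regulatory classes (the guideline caps
rind at 18 % w/w for grated packs).  Zero-rind samples exist for each
seasoning but carry no working process.  This module encodes that taxonomy,
the rind-class grouping rule, the replica manifest (including the packaged
replica-count fixture of the published design, 452 replicas) and the packaged
per-step selected-feature lists from the published screening.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "Seasoning",
    "Process",
    "RindClass",
    "SampleLabel",
    "SensorSpec",
    "DesignManifest",
    "SelectionFixture",
    "FEATURE_NAMES",
    "NONZERO_RIND_PCTS",
    "classify_rind",
    "build_manifest",
    "load_published_counts",
    "load_published_selection",
    "default_sensor_array",
]


class Seasoning(str, enum.Enum):
    """Ripening stage of the cheese."""

    M12 = "M12"
    M24 = "M24"


class Process(str, enum.Enum):
    """Rind working (cleaning) process; NONE marks zero-rind samples."""

    WR = "WR"
    SR = "SR"
    NONE = "NONE"


class RindClass(str, enum.Enum):
    """Regulatory grouping of the rind mass fraction."""

    LE18 = "LE18"  # <= 18 % w/w, guideline-compliant
    PCT19_26 = "PCT19_26"  # between 18 % and 26 %
    GT26 = "GT26"  # > 26 %


#: Canonical feature names, in canonical column order.
FEATURE_NAMES: tuple[str, ...] = (
    "delta_r",
    "deriv_extremum",
    "area_to_extremum",
    "total_area",
    "transition_time",
)

#: Non-zero nominal rind percentages prepared in the study design.
NONZERO_RIND_PCTS: tuple[float, ...] = (5, 16, 18, 20, 26, 32, 45, 55, 63, 100)


def classify_rind(rind_pct: float) -> RindClass:
    """Map a rind mass fraction (% w/w) to its regulatory class.

    Brackets are half-open so the 18 % guideline limit is itself compliant:
    ``<= 18`` -> LE18, ``(18, 26]`` -> PCT19_26, ``> 26`` -> GT26.

    Raises
    ------
    ValueError
        If ``rind_pct`` is outside [0, 100] or not a finite number.
    """
    pct = float(rind_pct)
    if not (0.0 <= pct <= 100.0):
        raise ValueError(
            f"rind_pct must be a percentage in [0, 100], got {rind_pct!r}"
        )
    if pct <= 18.0:
        return RindClass.LE18
    if pct <= 26.0:
        return RindClass.PCT19_26
    return RindClass.GT26


@dataclass(frozen=True)
class SampleLabel:
    """Three-level class annotation of one replica.

    ``rind_class`` is always the deterministic image of ``rind_pct`` under
    :func:`classify_rind`; ``process`` is NONE exactly for zero-rind samples.
    """

    seasoning: Seasoning
    process: Process
    rind_pct: float
    rind_class: RindClass = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "rind_class", classify_rind(self.rind_pct))
        if (self.process is Process.NONE) != (self.rind_pct == 0):
            raise ValueError(
                "process must be NONE if and only if rind_pct == 0; got "
                f"process={self.process.value}, rind_pct={self.rind_pct}"
            )


@dataclass(frozen=True)
class SensorSpec:
    """Static description of one array channel (metadata only)."""

    sensor_id: str
    polarity: str  # "n" or "p"
    morphology: str  # RGTO | nanowire | commercial
    operating_temp_C: float
    descriptor: str = ""

    def __post_init__(self) -> None:
        if self.polarity not in ("n", "p"):
            raise ValueError(f"polarity must be 'n' or 'p', got {self.polarity!r}")


def default_sensor_array() -> list[SensorSpec]:
    """The eight-channel array used throughout: seven n-type MOX channels and
    one p-type copper-oxide channel."""
    return [
        SensorSpec("RGTO_SnO2Au_400", "n", "RGTO", 400, "SnO2 + Au clusters, RGTO film"),
        SensorSpec("RGTO_SnO2_300", "n", "RGTO", 300, "SnO2 RGTO film, low temperature"),
        SensorSpec("RGTO_SnO2_400", "n", "RGTO", 400, "SnO2 RGTO film, high temperature"),
        SensorSpec("NW_SnO2Au_350", "n", "nanowire", 350, "SnO2 nanowires + Au clusters"),
        SensorSpec("NW_SnO2_350", "n", "nanowire", 350, "SnO2 nanowires"),
        SensorSpec("NW_CuO_400", "p", "nanowire", 400, "CuO nanowires (p-type)"),
        SensorSpec("TGS2611", "n", "commercial", 500, "Figaro TGS2611, natural gas"),
        SensorSpec("TGS2602", "n", "commercial", 500, "Figaro TGS2602, odorous gases"),
    ]


MANIFEST_COLUMNS = ("replica_id", "seasoning", "process", "rind_pct", "rind_class")


@dataclass
class DesignManifest:
    """Replica-level manifest: one row per acquisition replica."""

    rows: list[tuple[str, SampleLabel]]
    provenance: str = "custom"  # published_counts | full_design | custom

    def __post_init__(self) -> None:
        ids = [rid for rid, _ in self.rows]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate replica_id values: {dupes[:5]}")

    def __len__(self) -> int:
        return len(self.rows)

    def labels(self) -> dict[str, SampleLabel]:
        return dict(self.rows)

    def to_frame(self) -> pd.DataFrame:
        recs = [
            {
                "replica_id": rid,
                "seasoning": lab.seasoning.value,
                "process": lab.process.value,
                "rind_pct": lab.rind_pct,
                "rind_class": lab.rind_class.value,
            }
            for rid, lab in self.rows
        ]
        return pd.DataFrame(recs, columns=list(MANIFEST_COLUMNS))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, provenance: str = "custom") -> "DesignManifest":
        rows = [
            (
                str(r.replica_id),
                SampleLabel(Seasoning(r.seasoning), Process(r.process), float(r.rind_pct)),
            )
            for r in frame.itertuples(index=False)
        ]
        return cls(rows=rows, provenance=provenance)

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path, provenance: str = "custom") -> "DesignManifest":
        return cls.from_frame(pd.read_csv(path), provenance=provenance)


@dataclass(frozen=True)
class SelectionFixture:
    """One cascade step's published selected-feature list."""

    step: int
    entries: tuple[tuple[str, str], ...]

    def columns(self) -> list[str]:
        """Canonical ``{sensor_id}.{feature}`` column names."""
        return [f"{sid}.{feat}" for sid, feat in self.entries]


def _data_text(name: str) -> str:
    return resources.files("moxnose.data").joinpath(name).read_text()


def load_published_counts() -> dict:
    """Packaged replica-count fixture of the published design."""
    return json.loads(_data_text("published_counts.json"))


def load_published_selection(step: int) -> SelectionFixture:
    """Packaged verbatim per-step selected-feature list (steps 1-3)."""
    if step not in (1, 2, 3):
        raise ValueError(f"step must be 1, 2 or 3, got {step!r}")
    payload = json.loads(_data_text("published_selection.json"))
    entries = tuple((str(s), str(f)) for s, f in payload["steps"][str(step)])
    return SelectionFixture(step=step, entries=entries)


# Non-zero percentages falling in each rind class; used to spread the
# class-level fixture counts over concrete nominal percentages.
_CLASS_PCTS: dict[RindClass, tuple[float, ...]] = {
    RindClass.LE18: (5, 16, 18),
    RindClass.PCT19_26: (20, 26),
    RindClass.GT26: (32, 45, 55, 63, 100),
}


def _fmt_pct(pct: float) -> str:
    return f"{pct:g}"


def _expand_cell(
    seasoning: Seasoning, process: Process, pct: float, n: int, start: int = 1
) -> list[tuple[str, SampleLabel]]:
    label = SampleLabel(seasoning, process, pct)
    prefix = f"{seasoning.value}_{process.value}_{_fmt_pct(pct)}"
    return [(f"{prefix}_{k}", label) for k in range(start, start + n)]


def _expand_class_cell(
    seasoning: Seasoning, process: Process, rind_class: RindClass, n: int
) -> list[tuple[str, SampleLabel]]:
    # Round-robin the class-level count over the class's nominal percentages,
    # so every manifest row carries a concrete percentage of the design.
    pcts = _CLASS_PCTS[rind_class]
    base, extra = divmod(n, len(pcts))
    rows: list[tuple[str, SampleLabel]] = []
    for i, pct in enumerate(pcts):
        rows.extend(_expand_cell(seasoning, process, pct, base + (1 if i < extra else 0)))
    return rows


def build_manifest(
    mode: str = "published_counts",
    counts: pd.DataFrame | Iterable[Mapping] | None = None,
) -> DesignManifest:
    """Build a replica manifest.

    Parameters
    ----------
    mode
        ``"published_counts"`` reproduces the published replica counts exactly
        (452 rows, including 14 + 12 zero-rind replicas carrying process
        NONE); ``"full_design"`` enumerates 14 replicas for each of the 42
        sample kinds (588 rows); ``"custom"`` takes explicit per-cell counts.
    counts
        For ``custom`` mode: a DataFrame (or records) with columns
        ``seasoning, process, rind_pct, n``.
    """
    rows: list[tuple[str, SampleLabel]] = []
    if mode == "published_counts":
        fixture = load_published_counts()
        for seas_name, by_proc in fixture["cells"].items():
            for proc_name, by_class in by_proc.items():
                for class_name, n in by_class.items():
                    rows.extend(
                        _expand_class_cell(
                            Seasoning(seas_name),
                            Process(proc_name),
                            RindClass(class_name),
                            int(n),
                        )
                    )
        for seas_name, n in fixture["zero_rind"].items():
            rows.extend(_expand_cell(Seasoning(seas_name), Process.NONE, 0.0, int(n)))
    elif mode == "full_design":
        for seasoning in Seasoning:
            rows.extend(_expand_cell(seasoning, Process.NONE, 0.0, 14))
            for process in (Process.WR, Process.SR):
                for pct in NONZERO_RIND_PCTS:
                    rows.extend(_expand_cell(seasoning, process, float(pct), 14))
    elif mode == "custom":
        if counts is None:
            raise ValueError("custom mode requires a counts table")
        table = counts if isinstance(counts, pd.DataFrame) else pd.DataFrame(list(counts))
        if len(table) and (table["n"] < 0).any():
            bad = table.loc[table["n"] < 0]
            raise ValueError(f"negative replica counts are not allowed:\n{bad}")
        for rec in table.itertuples(index=False):
            rows.extend(
                _expand_cell(
                    Seasoning(rec.seasoning),
                    Process(rec.process),
                    float(rec.rind_pct),
                    int(rec.n),
                )
            )
    else:
        raise ValueError(
            f"mode must be 'published_counts', 'full_design' or 'custom', got {mode!r}"
        )
    return DesignManifest(rows=rows, provenance=mode)
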