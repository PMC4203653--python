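"""Parse TreeSAAP-style property results and build the PBS/PBR tables.

TreeSAAP scores every non-synonymous substitution by its effect on 31
physicochemical amino-acid properties, binning effect magnitudes into
categories 1-8 (7-8 are the most radical) with a per-property Z-score.  Its
output tree has two families: ``Substs/`` holds per-site records and
``Evpthwy/`` holds sliding-window series.

The on-disk grammar used here is a documented TSV dialect (the package's
fixture writer emits it and this parser consumes it):

* Substs file — one property per file::

      # property: <registry name>
      codon<TAB>category<TAB>z_score[<TAB>branch]
      7<TAB>8<TAB>3.50<TAB>A..B

* Evpthwy file — one property per file::

      # property: <registry name>
      from<TAB>to<TAB>z_cat1 ... z_cat8

Comment lines start with ``#``; blank lines are ignored.  Window starts must
be strictly increasing.

The *Properties By Site* (PBS) table keeps records in the configured magnitude
categories (7-8 by default) with |Z| at or above the cutoff (3.09, one-tailed
p = 0.001) and counts distinct qualifying properties per codon; *Properties By
Range* (PBR) does the analogous per-window summary, splitting property names
by direction of selection.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import PropertyRegistry, ThresholdConfig, DEFAULT_REGISTRY

__all__ = [
    "PropertyRecord",
    "PBSRow",
    "PBRRow",
    "EvpthwySeries",
    "parse_substs",
    "parse_evpthwy",
    "build_pbs",
    "pbs_statistics",
    "build_pbr",
    "export_window_plot_data",
]


class TreesaapParseError(ValueError):
    """Raised when a property result file cannot be interpreted."""


@dataclass(frozen=True)
class PropertyRecord:
    codon: int
    property: str
    category: int
    z_score: float
    branch: str | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.category <= 8:
            raise ValueError(f"category must be in 1..8, got {self.category}")


@dataclass(frozen=True)
class PBSRow:
    codon: int
    total: int
    properties: tuple[str, ...]  # names annotated with (+)/(-)


@dataclass(frozen=True)
class PBRRow:
    from_codon: int
    to_codon: int
    total: int
    properties_positive: tuple[str, ...]
    properties_negative: tuple[str, ...]


@dataclass
class EvpthwySeries:
    """Sliding-window Z-scores for one property: one row per window, one
    column per magnitude category 1-8."""

    property: str
    windows: list[tuple[int, int]]
    z: np.ndarray  # shape (n_windows, 8)


def _read_dialect_file(path: Path) -> tuple[str | None, list[list[str]]]:
    prop_name = None
    rows: list[list[str]] = []
    for raw in path.read_text(encoding="utf-8").splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            if line[1:].strip().lower().startswith("property:"):
                prop_name = line.split(":", 1)[1].strip()
            continue
        rows.append(raw.split("\t"))
    return prop_name, rows


def _collect_paths(paths) -> list[Path]:
    if isinstance(paths, (str, Path)):
        paths = [paths]
    out: list[Path] = []
    for p in paths:
        p = Path(p)
        if p.is_dir():
            out.extend(sorted(q for q in p.iterdir() if q.is_file()))
        else:
            out.append(p)
    return out


def parse_substs(
    paths, registry: PropertyRegistry = DEFAULT_REGISTRY
) -> list[PropertyRecord]:
    """Parse per-site property files (a path, a directory, or a list)."""
    records: list[PropertyRecord] = []
    for path in _collect_paths(paths):
        prop_name, rows = _read_dialect_file(path)
        if prop_name is None:
            raise TreesaapParseError(f"{path}: missing '# property:' header")
        try:
            prop = registry.resolve(prop_name)
        except KeyError as exc:
            raise TreesaapParseError(f"{path}: {exc.args[0]}") from None
        header_seen = False
        for cells in rows:
            if not header_seen and cells[0].strip().lower() == "codon":
                header_seen = True
                continue
            if len(cells) < 3:
                raise TreesaapParseError(f"{path}: expected >=3 columns, got {cells!r}")
            codon, category = int(cells[0]), int(cells[1])
            if not 1 <= category <= 8:
                raise TreesaapParseError(
                    f"{path}: category {category} outside 1..8 at codon {codon}"
                )
            branch = cells[3].strip() if len(cells) > 3 and cells[3].strip() else None
            records.append(
                PropertyRecord(
                    codon=codon, property=prop, category=category,
                    z_score=float(cells[2]), branch=branch,
                )
            )
    return records


def parse_evpthwy(
    paths, registry: PropertyRegistry = DEFAULT_REGISTRY
) -> list[EvpthwySeries]:
    """Parse sliding-window property files into per-property series."""
    series: list[EvpthwySeries] = []
    for path in _collect_paths(paths):
        prop_name, rows = _read_dialect_file(path)
        if prop_name is None:
            raise TreesaapParseError(f"{path}: missing '# property:' header")
        try:
            prop = registry.resolve(prop_name)
        except KeyError as exc:
            raise TreesaapParseError(f"{path}: {exc.args[0]}") from None
        windows: list[tuple[int, int]] = []
        zrows: list[list[float]] = []
        for cells in rows:
            if cells[0].strip().lower() == "from":
                if len(cells) < 10:
                    raise TreesaapParseError(
                        f"{path}: expected columns from, to, z_cat1..z_cat8; got {cells!r}"
                    )
                continue
            if len(cells) != 10:
                raise TreesaapParseError(
                    f"{path}: expected 10 columns (from, to, 8 category z), got {len(cells)}"
                )
            windows.append((int(cells[0]), int(cells[1])))
            zrows.append([float(c) for c in cells[2:]])
        starts = [w[0] for w in windows]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise TreesaapParseError(f"{path}: window starts not strictly increasing")
        series.append(
            EvpthwySeries(
                property=prop,
                windows=windows,
                z=np.array(zrows, dtype=float).reshape(len(windows), 8),
            )
        )
    return series


def _qualifies(category: int, z: float, thresholds: ThresholdConfig) -> str | None:
    """'(+)', '(-)' or None for one (category, z) observation."""
    if category not in thresholds.treesaap_categories:
        return None
    if z >= thresholds.treesaap_z:
        return "(+)"
    if z <= -thresholds.treesaap_z:
        return "(-)"
    return None


def build_pbs(
    records: list[PropertyRecord],
    thresholds: ThresholdConfig | None = None,
) -> list[PBSRow]:
    """Properties-By-Site table: per-codon distinct significant properties.

    A property significant on several branches at one codon counts once; the
    annotation carries the sign(s) observed.
    """
    thresholds = thresholds or ThresholdConfig()
    by_codon: dict[int, dict[str, set[str]]] = defaultdict(lambda: defaultdict(set))
    for rec in sorted(records, key=lambda r: (r.codon, r.property, r.z_score)):
        tag = _qualifies(rec.category, rec.z_score, thresholds)
        if tag is not None:
            by_codon[rec.codon][rec.property].add(tag)
    rows: list[PBSRow] = []
    for codon in sorted(by_codon):
        names = tuple(
            f"{prop} {''.join(sorted(tags))}" for prop, tags in sorted(by_codon[codon].items())
        )
        rows.append(PBSRow(codon=codon, total=len(names), properties=names))
    return rows


def pbs_statistics(pbs: list[PBSRow]) -> pd.DataFrame:
    """How many codons each property is selected at, across the dataset.

    The counts conserve the PBS totals: their sum equals the sum of the
    per-codon totals.
    """
    counts: dict[str, int] = defaultdict(int)
    for row in pbs:
        for annotated in row.properties:
            name = annotated.rsplit(" (", 1)[0]
            counts[name] += 1
    return pd.DataFrame(
        [{"property": k, "total": v} for k, v in sorted(counts.items())],
        columns=["property", "total"],
    )


def build_pbr(
    series: list[EvpthwySeries],
    thresholds: ThresholdConfig | None = None,
) -> list[PBRRow]:
    """Properties-By-Range table from the sliding-window series.

    For each window, a property is listed as positive (negative) when any of
    its configured-category Z-scores is at or above the +cutoff (at or below
    the -cutoff).  Windows with no qualifying property are omitted.
    """
    thresholds = thresholds or ThresholdConfig()
    cats = sorted(thresholds.treesaap_categories)
    by_window: dict[tuple[int, int], tuple[set[str], set[str]]] = defaultdict(
        lambda: (set(), set())
    )
    for s in series:
        for i, window in enumerate(s.windows):
            zs = [s.z[i, c - 1] for c in cats]
            if any(z >= thresholds.treesaap_z for z in zs):
                by_window[window][0].add(s.property)
            if any(z <= -thresholds.treesaap_z for z in zs):
                by_window[window][1].add(s.property)
    rows: list[PBRRow] = []
    for (lo, hi) in sorted(by_window):
        pos, neg = by_window[(lo, hi)]
        if not pos and not neg:
            continue
        rows.append(
            PBRRow(
                from_codon=lo,
                to_codon=hi,
                total=len(pos) + len(neg),
                properties_positive=tuple(sorted(pos)),
                properties_negative=tuple(sorted(neg)),
            )
        )
    return rows


def export_window_plot_data(series: list[EvpthwySeries], property: str) -> pd.DataFrame:
    """Sliding-window plot table for one property: window midpoint on the
    x-axis, one Z column per magnitude category.  Serializes to TSV for any
    plotting tool."""
    matches = [s for s in series if s.property == property]
    if not matches:
        available = sorted(s.property for s in series)
        raise KeyError(f"no windowed series for property {property!r}; have {available}")
    s = matches[0]
    rows = []
    for i, (lo, hi) in enumerate(s.windows):
        row = {"midpoint": (lo + hi) / 2.0, "from": lo, "to": hi}
        row.update({f"z_cat{c}": s.z[i, c - 1] for c in range(1, 9)})
        rows.append(row)
    cols = ["midpoint", "from", "to"] + [f"z_cat{c}" for c in range(1, 9)]
    return pd.DataFrame(rows, columns=cols)
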