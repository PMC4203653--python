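"""Combine per-program site calls into the Merged Results (MR) table.

The MR table takes the union of sites flagged by the codeml BEB analysis, the
Datamonkey common-sites intersection, and the TreeSAAP PBS table, marks which
sources detected each site, flags sites common to every supplied source, and
classifies each site by its radical-property count (NP) into the three-color
rendering scheme: red for NP < 2, green for 2 <= NP <= 5, blue for NP > 5.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .core import SelectionCall
from .treesaap import PBSRow

__all__ = ["MergedRow", "build_merged_table", "classify_np", "merged_table_to_frame"]

_UNSET = object()


@dataclass(frozen=True)
class MergedRow:
    codon: int
    in_paml: bool
    in_datamonkey: bool
    in_treesaap: bool
    common: bool
    total_properties: int
    property_names: tuple[str, ...]
    color_class: str


def classify_np(total_properties: int) -> str:
    """Color class for a site's radical-property count (NP).

    Breakpoints at 2 and 5, both green-inclusive: red below 2, green for
    2 through 5, blue above 5.
    """
    if total_properties < 0:
        raise ValueError(f"property count must be >= 0, got {total_properties}")
    if total_properties < 2:
        return "red"
    if total_properties <= 5:
        return "green"
    return "blue"


def build_merged_table(
    paml_calls: Sequence[SelectionCall] | None = None,
    datamonkey_sites: Iterable[int] | None = None,
    pbs_rows: Sequence[PBSRow] | None = None,
) -> list[MergedRow]:
    """One row per site appearing in any supplied source, ascending by codon.

    At least two of the three sources must be supplied (pass an empty
    collection for a source that ran but found nothing).  ``common`` is the
    conjunction of presence over the *supplied* sources only; property counts
    and names come from the PBS rows, defaulting to zero for sites the
    TreeSAAP analysis did not flag.
    """
    supplied = [s is not None for s in (paml_calls, datamonkey_sites, pbs_rows)]
    if sum(supplied) < 2:
        raise ValueError("build_merged_table needs at least two sources")

    paml_set = {c.site for c in paml_calls} if paml_calls is not None else None
    dm_set = set(datamonkey_sites) if datamonkey_sites is not None else None
    pbs_by_codon = {r.codon: r for r in pbs_rows} if pbs_rows is not None else None
    ts_set = set(pbs_by_codon) if pbs_by_codon is not None else None

    all_sites = set()
    for s in (paml_set, dm_set, ts_set):
        if s is not None:
            all_sites |= s

    rows: list[MergedRow] = []
    for codon in sorted(all_sites):
        presence = {
            "paml": codon in paml_set if paml_set is not None else None,
            "dm": codon in dm_set if dm_set is not None else None,
            "ts": codon in ts_set if ts_set is not None else None,
        }
        common = all(v for v in presence.values() if v is not None)
        pbs = pbs_by_codon.get(codon) if pbs_by_codon is not None else None
        total = pbs.total if pbs is not None else 0
        names = pbs.properties if pbs is not None else ()
        rows.append(
            MergedRow(
                codon=codon,
                in_paml=bool(presence["paml"]),
                in_datamonkey=bool(presence["dm"]),
                in_treesaap=bool(presence["ts"]),
                common=common,
                total_properties=total,
                property_names=names,
                color_class=classify_np(total),
            )
        )
    return rows


def merged_table_to_frame(rows: list[MergedRow]) -> pd.DataFrame:
    """CSV-ready MR table mirroring the integration platform's column roles."""
    return pd.DataFrame(
        [
            {
                "Codon": r.codon,
                "Datamonkey": r.in_datamonkey,
                "PAML M8Site": r.in_paml,
                "TreeSAAP": r.in_treesaap,
                "Common Sites": r.common,
                "Total": r.total_properties,
                "Properties (7-8) (+)": "; ".join(r.property_names),
                "ColorClass": r.color_class,
            }
            for r in rows
        ],
        columns=[
            "Codon", "Datamonkey", "PAML M8Site", "TreeSAAP",
            "Common Sites", "Total", "Properties (7-8) (+)", "ColorClass",
        ],
    )
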