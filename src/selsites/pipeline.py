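"""End-to-end orchestration: parse every program's outputs, filter, intersect,
merge and classify.  This is the library-level equivalent of running the CLI
subcommands in sequence and is what the demo workflow executes."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import datamonkey as dm
from . import paml, treesaap
from .core import Method, SelectionCall, Sign, ThresholdConfig
from .merge import MergedRow, build_merged_table, merged_table_to_frame

__all__ = ["PipelineResult", "run_integration"]

DM_METHODS = (Method.SLAC, Method.FEL, Method.REL, Method.MEME, Method.FUBAR)


@dataclass
class PipelineResult:
    paml_calls: list[SelectionCall]
    datamonkey_calls: dict[Method, list[SelectionCall]]
    datamonkey_common: list[int]
    pbs_rows: list[treesaap.PBSRow]
    merged: list[MergedRow]

    @property
    def merged_frame(self) -> pd.DataFrame:
        return merged_table_to_frame(self.merged)

    @property
    def common_sites(self) -> list[int]:
        return [r.codon for r in self.merged if r.common]


def run_integration(
    codeml_alt_path: str | Path,
    datamonkey_paths: dict[Method | str, str | Path],
    treesaap_substs: str | Path,
    thresholds: ThresholdConfig | None = None,
    alt_model: str = "M8",
    sign: Sign = Sign.POSITIVE,
) -> PipelineResult:
    """Parse -> filter -> intersect -> merge -> classify.

    ``codeml_alt_path`` is the alternative-model codeml result (M8 by
    default); ``datamonkey_paths`` maps each method to its site table;
    ``treesaap_substs`` is the Substs directory (or file list).
    """
    thresholds = thresholds or ThresholdConfig()

    fit = paml.parse_codeml_result(codeml_alt_path, expected_model=alt_model)
    if isinstance(fit, list):
        fit = next(f for f in fit if f.model_id == alt_model)
    paml_calls = paml.extract_beb_sites(fit, pp_cutoff=thresholds.beb_pp)

    dm_calls: dict[Method, list[SelectionCall]] = {}
    for method, path in datamonkey_paths.items():
        method = Method(method)
        table = dm.parse_method_table(path, method)
        dm_calls[method] = dm.filter_sites(table, thresholds, sign)
    dm_common = dm.common_sites(list(dm_calls.values()))

    records = treesaap.parse_substs(treesaap_substs)
    pbs_rows = treesaap.build_pbs(records, thresholds)

    merged = build_merged_table(
        paml_calls=paml_calls, datamonkey_sites=dm_common, pbs_rows=pbs_rows
    )
    return PipelineResult(
        paml_calls=paml_calls,
        datamonkey_calls=dm_calls,
        datamonkey_common=dm_common,
        pbs_rows=pbs_rows,
        merged=merged,
    )
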