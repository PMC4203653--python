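"""Parse Datamonkey per-method site tables and filter selected sites.

Each of SLAC, FEL, REL, MEME and FUBAR exports one delimited table with one
row per codon site.  Column headers have drifted across server versions, so
every method has a :class:`Dialect` mapping logical roles (site, p-value,
rate columns, Bayes factors, posteriors) onto concrete header names; the
built-in dialects describe one frozen layout and can be overridden per file.

Filtering follows the server defaults: p <= 0.1 for SLAC, FEL and MEME,
posterior >= 0.9 for FUBAR, Bayes factor >= 50 for REL, all boundaries
inclusive.  For SLAC, FEL and FUBAR the direction of selection comes from the
row's rate comparison (nonsynonymous > synonymous means positive); rows where
the rates tie are excluded from both signs.  MEME detects episodic positive
selection only.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .core import (
    Method,
    SelectionCall,
    Sign,
    StatisticKind,
    ThresholdConfig,
    make_call,
)

__all__ = [
    "Dialect",
    "MethodTable",
    "DEFAULT_DIALECTS",
    "parse_method_table",
    "filter_sites",
    "common_sites",
    "recommend_methods",
    "MethodRecommendation",
]

DATAMONKEY_METHODS = (Method.SLAC, Method.FEL, Method.REL, Method.MEME, Method.FUBAR)


class TableParseError(ValueError):
    """Raised when a method table cannot be interpreted."""


@dataclass(frozen=True)
class Dialect:
    """Maps logical column roles to the header names of one export layout."""

    site: str = "Site"
    p_value: str | None = None          # SLAC, FEL, MEME
    rate_diff: str | None = None        # SLAC: signed dN-dS
    rate_syn: str | None = None         # FEL alpha / FUBAR alpha
    rate_nonsyn: str | None = None      # FEL beta / FUBAR beta
    bf_positive: str | None = None      # REL
    bf_negative: str | None = None      # REL
    posterior_positive: str | None = None  # FUBAR
    posterior_negative: str | None = None  # FUBAR

    def required_columns(self) -> list[str]:
        return [c for c in (
            self.site, self.p_value, self.rate_diff, self.rate_syn,
            self.rate_nonsyn, self.bf_positive, self.bf_negative,
            self.posterior_positive, self.posterior_negative,
        ) if c is not None]


DEFAULT_DIALECTS: dict[Method, Dialect] = {
    Method.SLAC: Dialect(site="Site", p_value="P-value", rate_diff="dN-dS"),
    Method.FEL: Dialect(site="Site", p_value="P-value", rate_syn="alpha", rate_nonsyn="beta"),
    Method.REL: Dialect(
        site="Site",
        bf_positive="Bayes Factor [omega>1]",
        bf_negative="Bayes Factor [omega<1]",
    ),
    Method.MEME: Dialect(site="Site", p_value="p-value"),
    Method.FUBAR: Dialect(
        site="Site",
        rate_syn="alpha",
        rate_nonsyn="beta",
        posterior_positive="Prob[alpha<beta]",
        posterior_negative="Prob[alpha>beta]",
    ),
}


@dataclass
class MethodTable:
    method: Method
    rows: pd.DataFrame
    dialect: Dialect

    def __post_init__(self) -> None:
        sites = self.rows[self.dialect.site].tolist() if len(self.rows) else []
        if any(b <= a for a, b in zip(sites, sites[1:])):
            raise TableParseError(f"{self.method.value}: site numbers not strictly increasing")

    @property
    def sites(self) -> list[int]:
        return self.rows[self.dialect.site].tolist()


def _sniff_delimiter(path: Path) -> str:
    first = path.read_text(encoding="utf-8").splitlines()[0] if path.stat().st_size else ""
    return "\t" if "\t" in first else ","


def parse_method_table(
    path: str | Path, method: Method | str, dialect: Dialect | None = None
) -> MethodTable:
    """Read one per-method site table (CSV; tab-delimited auto-detected)."""
    method = Method(method)
    if method not in DATAMONKEY_METHODS:
        raise ValueError(f"{method.value} is not a Datamonkey site method")
    dialect = dialect or DEFAULT_DIALECTS[method]
    path = Path(path)
    sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, dtype=str)
    missing = [c for c in dialect.required_columns() if c not in df.columns]
    if missing:
        raise TableParseError(
            f"{path}: missing required column(s) {missing}; available: {list(df.columns)}"
        )
    for col in dialect.required_columns():
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()][0]
            raise TableParseError(
                f"{path}: non-numeric value in column {col!r} at data row {bad + 1}"
            ) from None
    df[dialect.site] = df[dialect.site].astype(int)
    return MethodTable(method=method, rows=df, dialect=dialect)


def _row_sign(row: pd.Series, dialect: Dialect) -> Sign | None:
    """Direction of selection from the row's rate columns; None on a tie."""
    if dialect.rate_diff is not None:
        diff = row[dialect.rate_diff]
    else:
        diff = row[dialect.rate_nonsyn] - row[dialect.rate_syn]
    if diff > 0:
        return Sign.POSITIVE
    if diff < 0:
        return Sign.NEGATIVE
    return None


def filter_sites(
    table: MethodTable, thresholds: ThresholdConfig, sign: Sign | str
) -> list[SelectionCall]:
    """Significant sites of one method for one direction of selection."""
    sign = Sign(sign)
    method, d = table.method, table.dialect
    if method is Method.MEME and sign is Sign.NEGATIVE:
        raise ValueError("MEME detects episodic positive selection only")

    calls: list[SelectionCall] = []
    for _, row in table.rows.iterrows():
        site = int(row[d.site])
        if method in (Method.SLAC, Method.FEL):
            cutoff = thresholds.slac_p if method is Method.SLAC else thresholds.fel_p
            if row[d.p_value] <= cutoff and _row_sign(row, d) is sign:
                calls.append(make_call(site, method, sign, StatisticKind.P_VALUE,
                                       row[d.p_value], cutoff))
        elif method is Method.MEME:
            if row[d.p_value] <= thresholds.meme_p:
                calls.append(make_call(site, method, sign, StatisticKind.P_VALUE,
                                       row[d.p_value], thresholds.meme_p))
        elif method is Method.REL:
            col = d.bf_positive if sign is Sign.POSITIVE else d.bf_negative
            if row[col] >= thresholds.rel_bf:
                calls.append(make_call(site, method, sign, StatisticKind.BAYES_FACTOR,
                                       row[col], thresholds.rel_bf))
        elif method is Method.FUBAR:
            col = d.posterior_positive if sign is Sign.POSITIVE else d.posterior_negative
            if row[col] >= thresholds.fubar_pp and _row_sign(row, d) is sign:
                calls.append(make_call(site, method, sign, StatisticKind.POSTERIOR,
                                       row[col], thresholds.fubar_pp))
    return calls


def common_sites(call_lists: list[list[SelectionCall]]) -> list[int]:
    """Sites detected by every provided method (ascending).

    With a single list this is just that list's sites; the operation is the
    intersection over the site sets of all lists.
    """
    if not call_lists:
        raise ValueError("common_sites requires at least one call list")
    site_sets = [{c.site for c in calls} for calls in call_lists]
    common = set.intersection(*site_sets)
    return sorted(common)


@dataclass(frozen=True)
class MethodRecommendation:
    method: Method
    recommended: bool
    note: str


def recommend_methods(n_sequences: int) -> list[MethodRecommendation]:
    """Dataset-size guidance for choosing among the site methods.

    SLAC suits large datasets (over 40 sequences), REL intermediate ones
    (20-40), FEL intermediate-to-large (over 50); FUBAR scales to very large
    datasets and MEME targets episodic selection with no stated size bound.
    """
    if n_sequences < 2:
        raise ValueError(f"need at least 2 sequences, got {n_sequences}")
    n = n_sequences
    return [
        MethodRecommendation(Method.SLAC, n > 40, "large datasets (over 40 sequences)"),
        MethodRecommendation(Method.REL, 20 <= n <= 40, "intermediate datasets (20-40 sequences)"),
        MethodRecommendation(Method.FEL, n > 50, "intermediate to large datasets (over 50 sequences)"),
        MethodRecommendation(Method.FUBAR, True, "very large datasets; fast approximate Bayesian"),
        MethodRecommendation(Method.MEME, True, "episodic positive selection; no size bound"),
    ]
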