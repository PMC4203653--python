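"""Shared domain types, default thresholds, the amino-acid property registry
and the statistical primitives used by every downstream stage.

The defaults collected in :class:`ThresholdConfig` are the standard cutoffs of
the upstream selection programs: an LRT significance level of 0.05 for the
codeml site-model comparisons; p = 0.1 for SLAC, FEL and MEME, a posterior
probability of 0.9 for FUBAR and a Bayes factor of 50 for REL (the Datamonkey
server defaults); and a |Z| >= 3.09 cutoff (one-tailed p = 0.001) restricted to
magnitude categories 7-8 for TreeSAAP radical property changes.  All boundary
comparisons are inclusive: a REL site with a Bayes factor of exactly 50 passes.
"""

from __future__ import annotations

import dataclasses
import enum
import importlib.resources
from dataclasses import dataclass, field

from scipy import stats as _stats

__all__ = [
    "Method",
    "Sign",
    "StatisticKind",
    "ThresholdConfig",
    "PropertyRegistry",
    "SelectionCall",
    "chi_square_survival",
    "z_critical",
    "is_significant",
]


class Method(str, enum.Enum):
    """Selection-analysis sources whose site calls the package integrates."""

    PAML_M2A = "PAML-M2a"
    PAML_M8 = "PAML-M8"
    SLAC = "SLAC"
    FEL = "FEL"
    REL = "REL"
    MEME = "MEME"
    FUBAR = "FUBAR"
    TREESAAP = "TreeSAAP"


class Sign(str, enum.Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"


class StatisticKind(str, enum.Enum):
    P_VALUE = "p-value"
    POSTERIOR = "posterior"
    BAYES_FACTOR = "bayes-factor"
    Z_SCORE = "z-score"


@dataclass(frozen=True)
class ThresholdConfig:
    """Significance cutoffs for every integrated method.

    Probability-like cutoffs must lie in (0, 1); the Bayes-factor and Z-score
    cutoffs must be positive; the TreeSAAP category set must be a subset of
    {1..8}.
    """

    paml_alpha: float = 0.05
    beb_pp: float = 0.95
    slac_p: float = 0.1
    fel_p: float = 0.1
    meme_p: float = 0.1
    fubar_pp: float = 0.9
    rel_bf: float = 50.0
    treesaap_z: float = 3.09
    treesaap_categories: frozenset[int] = frozenset({7, 8})

    def __post_init__(self) -> None:
        for name in ("paml_alpha", "beb_pp", "slac_p", "fel_p", "meme_p", "fubar_pp"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v!r}")
        if self.rel_bf <= 0:
            raise ValueError(f"rel_bf must be > 0, got {self.rel_bf!r}")
        if self.treesaap_z <= 0:
            raise ValueError(f"treesaap_z must be > 0, got {self.treesaap_z!r}")
        cats = frozenset(int(c) for c in self.treesaap_categories)
        if not cats or not cats <= frozenset(range(1, 9)):
            raise ValueError(
                f"treesaap_categories must be a non-empty subset of 1..8, got {cats!r}"
            )
        object.__setattr__(self, "treesaap_categories", cats)

    def replace(self, **kwargs) -> "ThresholdConfig":
        return dataclasses.replace(self, **kwargs)

    @classmethod
    def from_mapping(cls, mapping: dict) -> "ThresholdConfig":
        """Build a config from a dict (e.g. a parsed YAML file).

        Unknown keys are rejected so typos in config files fail loudly.
        """
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown threshold keys: {sorted(unknown)}")
        kwargs = dict(mapping)
        if "treesaap_categories" in kwargs:
            kwargs["treesaap_categories"] = frozenset(kwargs["treesaap_categories"])
        return cls(**kwargs)


def _normalize_property(name: str) -> str:
    return " ".join(name.split()).casefold()


class PropertyRegistry:
    """Registry of the 31 amino-acid properties scored for radical change.

    Lookup is case- and whitespace-insensitive; ``resolve`` returns the
    canonical name or raises ``KeyError`` with the nearest match as a hint.
    """

    def __init__(self, names: list[str] | None = None):
        if names is None:
            names = _load_default_properties()
        canonical: dict[str, str] = {}
        for name in names:
            key = _normalize_property(name)
            if key in canonical:
                raise ValueError(f"duplicate property name after normalization: {name!r}")
            canonical[key] = name
        self._by_key = canonical
        self.names: tuple[str, ...] = tuple(canonical.values())

    def __len__(self) -> int:
        return len(self.names)

    def __contains__(self, name: str) -> bool:
        return _normalize_property(name) in self._by_key

    def resolve(self, name: str) -> str:
        key = _normalize_property(name)
        try:
            return self._by_key[key]
        except KeyError:
            hint = self._nearest(key)
            raise KeyError(
                f"unknown amino-acid property {name!r}"
                + (f" (did you mean {hint!r}?)" if hint else "")
            ) from None

    def _nearest(self, key: str) -> str | None:
        import difflib

        matches = difflib.get_close_matches(key, list(self._by_key), n=1, cutoff=0.5)
        return self._by_key[matches[0]] if matches else None


def _load_default_properties() -> list[str]:
    text = (
        importlib.resources.files("selsites.data")
        .joinpath("aa_properties.txt")
        .read_text(encoding="utf-8")
    )
    return [ln.strip() for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]


@dataclass(frozen=True)
class SelectionCall:
    """One per-site verdict from one method.

    ``site`` is the 1-based codon position in the analysis alignment.
    ``significant`` is recomputed from (kind, value, threshold); callers should
    construct instances through :func:`make_call` to keep that invariant.
    """

    site: int
    method: Method
    sign: Sign
    statistic_kind: StatisticKind
    statistic_value: float
    threshold_applied: float
    significant: bool
    residue: str | None = None

    def __post_init__(self) -> None:
        if self.site < 1:
            raise ValueError(f"site must be >= 1, got {self.site}")


def make_call(
    site: int,
    method: Method | str,
    sign: Sign | str,
    kind: StatisticKind | str,
    value: float,
    threshold: float,
    residue: str | None = None,
) -> SelectionCall:
    """Construct a SelectionCall with ``significant`` derived from the rule."""
    method = Method(method)
    sign = Sign(sign)
    kind = StatisticKind(kind)
    return SelectionCall(
        site=site,
        method=method,
        sign=sign,
        statistic_kind=kind,
        statistic_value=float(value),
        threshold_applied=float(threshold),
        significant=is_significant(kind, value, threshold),
        residue=residue,
    )


def chi_square_survival(stat: float, df: int) -> float:
    """Upper-tail probability P(X >= stat) of a chi-square variable.

    Used for likelihood-ratio tests; ``df`` is limited to 1..64 which covers
    every model comparison in scope.
    """
    if stat < 0:
        raise ValueError(f"chi-square statistic must be >= 0, got {stat!r}")
    if not isinstance(df, (int,)) or isinstance(df, bool):
        raise ValueError(f"df must be a positive integer, got {df!r}")
    if not 1 <= df <= 64:
        raise ValueError(f"df must be in 1..64, got {df}")
    return float(_stats.chi2.sf(stat, df))


def z_critical(alpha: float) -> float:
    """Upper-tail standard-normal quantile: z such that P(Z >= z) = alpha."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha!r}")
    return float(_stats.norm.isf(alpha))


def is_significant(kind: StatisticKind | str, value: float, threshold: float) -> bool:
    """Apply the per-statistic comparison rule (all boundaries inclusive).

    p-value: value <= threshold; posterior and Bayes factor: value >=
    threshold; Z-score: |value| >= threshold (the sign carries the direction
    of selection, the magnitude the evidence).
    """
    kind = StatisticKind(kind)
    if kind is StatisticKind.P_VALUE:
        return value <= threshold
    if kind in (StatisticKind.POSTERIOR, StatisticKind.BAYES_FACTOR):
        return value >= threshold
    if kind is StatisticKind.Z_SCORE:
        return abs(value) >= threshold
    raise ValueError(f"unknown statistic kind: {kind!r}")  # pragma: no cover


DEFAULT_THRESHOLDS = ThresholdConfig()
DEFAULT_REGISTRY = PropertyRegistry()
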