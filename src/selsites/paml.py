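"""Parse codeml site-model result files and run likelihood-ratio tests.

Only the site-specific models M0, M1a, M2a, M3, M7 and M8 are handled.  The
parser is keyed on the stable tokens of the PAML 4.x main result layout —
``Model N:`` headers, the ``lnL(ntime: .. np: ..):`` line, and the
``Bayes Empirical Bayes (BEB)`` / ``Positively selected sites`` block — and is
whitespace-tolerant everywhere else.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .core import (
    Method,
    SelectionCall,
    Sign,
    StatisticKind,
    chi_square_survival,
    make_call,
)

__all__ = [
    "ModelFit",
    "LRTResult",
    "BEBSite",
    "parse_codeml_result",
    "likelihood_ratio_test",
    "extract_beb_sites",
    "tabulate_models",
    "SUPPORTED_PAIRS",
]

SITE_MODELS = ("M0", "M1a", "M2a", "M3", "M7", "M8")
ALTERNATIVE_MODELS = ("M2a", "M8")
#: LRT pairings (null, alternative) supported by the site-model framework.
SUPPORTED_PAIRS = (("M0", "M3"), ("M1a", "M2a"), ("M7", "M8"))

# codeml prints "Model 0: one-ratio", "Model 1: NearlyNeutral", etc.
_MODEL_NUMBER_TO_ID = {0: "M0", 1: "M1a", 2: "M2a", 3: "M3", 7: "M7", 8: "M8"}

_LNL_RE = re.compile(
    r"lnL\(ntime:\s*(?P<ntime>\d+)\s+np:\s*(?P<np>\d+)\):\s*(?P<lnl>-?\d+(?:\.\d+)?)"
)
_MODEL_RE = re.compile(r"^Model\s+(?P<num>\d+)\s*:", re.MULTILINE)
_KAPPA_RE = re.compile(r"kappa\s*\(ts/tv\)\s*=\s*(-?\d+(?:\.\d+)?)")
_PARAM_RE = re.compile(r"\(?\b(?P<key>w\d?|p\d|[pq])\s*\)?\s*=\s*(?P<val>-?\d+(?:\.\d+)?)")
_BEB_ROW_RE = re.compile(
    r"^\s*(?P<site>\d+)\s+(?P<res>[A-Z\-\*])\s+(?P<pp>[01](?:\.\d+)?)\*{0,2}"
    r"(?:\s+(?P<omega>-?\d+(?:\.\d+)?)(?:\s*\+-\s*\d+(?:\.\d+)?)?)?\s*$"
)


class CodemlParseError(ValueError):
    """Raised when a codeml result file cannot be interpreted."""


@dataclass(frozen=True)
class BEBSite:
    site: int
    residue: str
    posterior: float
    mean_omega: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.posterior <= 1.0:
            raise ValueError(f"BEB posterior must be in [0,1], got {self.posterior}")


@dataclass
class ModelFit:
    """One codeml site-model fit: likelihood, parameter estimates, BEB sites."""

    model_id: str
    lnL: float
    np: int
    ntime: int | None = None
    params: dict[str, float] = field(default_factory=dict)
    beb_sites: list[BEBSite] = field(default_factory=list)
    source_path: str = ""

    def __post_init__(self) -> None:
        if self.model_id not in SITE_MODELS:
            raise ValueError(f"unknown site model {self.model_id!r}")
        if self.np < 1:
            raise ValueError(f"np must be >= 1, got {self.np}")
        if self.beb_sites and self.model_id not in ALTERNATIVE_MODELS:
            raise ValueError(f"BEB sites present on null model {self.model_id}")
        props = [v for k, v in self.params.items() if re.fullmatch(r"p\d", k)]
        if props and abs(sum(props) - 1.0) > 1e-4:
            raise ValueError(f"class proportions sum to {sum(props)}, expected 1")


@dataclass(frozen=True)
class LRTResult:
    null_model: str
    alt_model: str
    statistic: float
    df: int
    p_value: float
    alpha: float
    significant: bool


def parse_codeml_result(
    path: str | Path, expected_model: str | None = None
) -> ModelFit | list[ModelFit]:
    """Parse a codeml main result file into one or more :class:`ModelFit`.

    NSsites batch files containing several ``Model N:`` sections yield a list;
    a single-model file yields one fit.  A file with no model header is
    accepted only when ``expected_model`` names the model it contains.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if "lnL(" not in text:
        raise CodemlParseError(f"{path}: no 'lnL(ntime: ... np: ...)' line found")

    headers = list(_MODEL_RE.finditer(text))
    if not headers:
        if expected_model is None:
            raise CodemlParseError(
                f"{path}: no 'Model N:' header and no expected_model given"
            )
        return _parse_section(text, expected_model, path, base_line=1)

    fits: list[ModelFit] = []
    for i, m in enumerate(headers):
        start = m.start()
        end = headers[i + 1].start() if i + 1 < len(headers) else len(text)
        num = int(m.group("num"))
        model_id = _MODEL_NUMBER_TO_ID.get(num)
        if model_id is None:
            raise CodemlParseError(f"{path}: unsupported site model number {num}")
        base_line = text.count("\n", 0, start) + 1
        fits.append(_parse_section(text[start:end], model_id, path, base_line))

    if expected_model is not None:
        matching = [f for f in fits if f.model_id == expected_model]
        if not matching:
            raise CodemlParseError(
                f"{path}: expected model {expected_model}, found "
                f"{[f.model_id for f in fits]}"
            )
        if len(matching) == 1 and len(fits) == 1:
            return matching[0]
        return matching if len(matching) > 1 else matching[0]
    return fits if len(fits) > 1 else fits[0]


def _parse_section(text: str, model_id: str, path: Path, base_line: int) -> ModelFit:
    m = _LNL_RE.search(text)
    if m is None:
        raise CodemlParseError(f"{path}: model {model_id}: missing lnL line")
    lnl = float(m.group("lnl"))
    np_ = int(m.group("np"))
    ntime = int(m.group("ntime"))

    # Parameter estimates: kappa plus whatever named estimates the model block
    # prints (w, w0..w2, p0..p2, beta p and q).
    beb_start = text.find("Bayes Empirical Bayes")
    param_region = text[m.end() : beb_start if beb_start >= 0 else len(text)]
    params: dict[str, float] = {}
    km = _KAPPA_RE.search(param_region)
    if km:
        params["kappa"] = float(km.group(1))
    for pm in _PARAM_RE.finditer(param_region):
        params[pm.group("key")] = float(pm.group("val"))

    beb_sites = _parse_beb(text, path, base_line) if beb_start >= 0 else []
    return ModelFit(
        model_id=model_id,
        lnL=lnl,
        np=np_,
        ntime=ntime,
        params=params,
        beb_sites=beb_sites,
        source_path=str(path),
    )


def _parse_beb(text: str, path: Path, base_line: int) -> list[BEBSite]:
    anchor = text.find("Positively selected sites")
    if anchor < 0:
        return []
    sites: list[BEBSite] = []
    lines_before = text.count("\n", 0, anchor)
    in_rows = False
    for offset, line in enumerate(text[anchor:].splitlines()):
        stripped = line.strip()
        if not stripped:
            if in_rows:
                break
            continue
        if stripped.startswith(("Positively", "(amino", "Pr(w>1)")):
            continue
        m = _BEB_ROW_RE.match(line)
        if m is None:
            lineno = base_line + lines_before + offset
            raise CodemlParseError(f"{path}: line {lineno}: malformed BEB row: {line!r}")
        in_rows = True
        sites.append(
            BEBSite(
                site=int(m.group("site")),
                residue=m.group("res"),
                posterior=float(m.group("pp")),
                mean_omega=float(m.group("omega")) if m.group("omega") else None,
            )
        )
    return sites


def likelihood_ratio_test(null: ModelFit, alt: ModelFit, alpha: float = 0.05) -> LRTResult:
    """LRT of a null site model against its alternative.

    The statistic 2*(lnL_alt - lnL_null) is clamped at zero (the alternative
    nests the null, so a negative difference is optimizer noise) and compared
    to a chi-square with df = np_alt - np_null: 2 for M1a/M2a and M7/M8,
    4 for M0/M3.
    """
    if (null.model_id, alt.model_id) not in SUPPORTED_PAIRS:
        raise ValueError(
            f"unsupported LRT pairing ({null.model_id}, {alt.model_id}); "
            f"supported: {SUPPORTED_PAIRS}"
        )
    if alt.np <= null.np:
        raise ValueError(
            f"alternative np ({alt.np}) must exceed null np ({null.np}); corrupt inputs?"
        )
    statistic = max(0.0, 2.0 * (alt.lnL - null.lnL))
    df = alt.np - null.np
    p = chi_square_survival(statistic, df)
    return LRTResult(
        null_model=null.model_id,
        alt_model=alt.model_id,
        statistic=statistic,
        df=df,
        p_value=p,
        alpha=alpha,
        significant=p <= alpha,
    )


def extract_beb_sites(fit: ModelFit, pp_cutoff: float = 0.95) -> list[SelectionCall]:
    """Positively selected sites from an alternative model's BEB block.

    Significance is recomputed from the numeric posterior against
    ``pp_cutoff``; the asterisk flags codeml prints are ignored.
    """
    if fit.model_id not in ALTERNATIVE_MODELS:
        raise ValueError(
            f"BEB extraction requires an alternative model (M2a/M8), got {fit.model_id}"
        )
    method = Method.PAML_M8 if fit.model_id == "M8" else Method.PAML_M2A
    calls = [
        make_call(
            site=s.site,
            method=method,
            sign=Sign.POSITIVE,
            kind=StatisticKind.POSTERIOR,
            value=s.posterior,
            threshold=pp_cutoff,
            residue=s.residue,
        )
        for s in sorted(fit.beb_sites, key=lambda s: s.site)
        if s.posterior >= pp_cutoff
    ]
    return calls


def tabulate_models(fits: list[ModelFit]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build the omega/parameter table and the lnL table, one row per model.

    The lnL table has columns (model, np, lnL); the omega table has the model
    id followed by the union of parameter names in a deterministic order.
    """
    seen: set[str] = set()
    for f in fits:
        if f.model_id in seen:
            raise ValueError(f"duplicate model in tabulation: {f.model_id}")
        seen.add(f.model_id)

    lnl_table = pd.DataFrame(
        [{"model": f.model_id, "np": f.np, "lnL": f.lnL} for f in fits],
        columns=["model", "np", "lnL"],
    )
    param_names: list[str] = []
    for f in fits:
        for k in f.params:
            if k not in param_names:
                param_names.append(k)
    omega_rows = [{"model": f.model_id, **{k: f.params.get(k) for k in param_names}} for f in fits]
    omega_table = pd.DataFrame(omega_rows, columns=["model", *param_names])
    return omega_table, lnl_table
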