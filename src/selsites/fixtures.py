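"""Deterministic generators for every input family the pipeline consumes.

These writers emit codeml result files, Datamonkey method tables, TreeSAAP
Evpthwy/Substs trees, codon alignments and toy PDB files with *planted*
selection signals: a :class:`FixtureSpec` states exactly which sites each
method must call (and with how many radical properties), and the writers
guarantee that parsing + filtering recovers the plant exactly.  Non-planted
statistics are drawn from seeded distributions strictly on the non-significant
side of every cutoff (with a wide margin), so recovery is exact rather than
probabilistic.  The same seed always produces byte-identical files.
"""

from __future__ import annotations

import re
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .core import DEFAULT_REGISTRY, Method, Sign, ThresholdConfig

__all__ = [
    "PlantedSite",
    "FixtureSpec",
    "canonical_spec",
    "random_spec",
    "write_codeml_fixture",
    "write_datamonkey_fixture",
    "write_treesaap_fixture",
    "write_alignment_fixture",
    "write_pdb_fixture",
    "write_workspace",
]

NULL_MODELS = ("M0", "M1a", "M7")
_STOP_CODONS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = sorted(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in _STOP_CODONS
)
_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class PlantedSite:
    """What the fixture plants at one codon site.

    ``methods`` lists the analyses that must call the site significant;
    ``n_properties`` is the number of radical amino-acid properties the
    TreeSAAP fixture attaches (ignored unless TreeSAAP is planted).
    """

    methods: frozenset[Method]
    sign: Sign = Sign.POSITIVE
    n_properties: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "methods", frozenset(Method(m) for m in self.methods))
        if Method.MEME in self.methods and self.sign is Sign.NEGATIVE:
            raise ValueError("MEME cannot be planted with negative selection")
        if Method.TREESAAP in self.methods and self.n_properties < 1:
            raise ValueError("a TreeSAAP plant needs n_properties >= 1")


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 0
    n_sites: int = 300
    n_sequences: int = 25
    planted_sites: dict[int, PlantedSite] = field(default_factory=dict)
    pdb_offset: int = 1
    pdb_deletions: tuple[int, ...] = ()
    chain_id: str = "A"

    def __post_init__(self) -> None:
        bad = [s for s in self.planted_sites if not 1 <= s <= self.n_sites]
        if bad:
            raise ValueError(f"planted sites outside 1..{self.n_sites}: {bad}")

    def rng(self, label: str) -> np.random.Generator:
        """Independent, reproducible stream per output file."""
        return np.random.default_rng(
            (self.seed * 2654435761 + zlib.crc32(label.encode())) % 2**31
        )

    def sites_for(self, method: Method, sign: Sign | None = None) -> list[int]:
        return sorted(
            s for s, p in self.planted_sites.items()
            if method in p.methods and (sign is None or p.sign is sign)
        )


def canonical_spec(seed: int = 0) -> FixtureSpec:
    """The demo plant: sites 110, 172, 202 and 231 called by every method
    (so the cross-method common set is exactly those four), plus single- and
    two-method extras and one negatively selected site."""
    all_methods = frozenset(
        {Method.SLAC, Method.FEL, Method.REL, Method.MEME, Method.FUBAR,
         Method.PAML_M8, Method.TREESAAP}
    )
    dm_neg = frozenset({Method.SLAC, Method.FEL, Method.REL, Method.FUBAR})
    return FixtureSpec(
        seed=seed,
        n_sites=300,
        n_sequences=25,
        planted_sites={
            110: PlantedSite(all_methods, Sign.POSITIVE, n_properties=6),
            172: PlantedSite(all_methods, Sign.POSITIVE, n_properties=4),
            202: PlantedSite(all_methods, Sign.POSITIVE, n_properties=1),
            231: PlantedSite(all_methods, Sign.POSITIVE, n_properties=2),
            50: PlantedSite(frozenset({Method.MEME}), Sign.POSITIVE),
            90: PlantedSite(
                frozenset({Method.PAML_M8, Method.TREESAAP}), Sign.POSITIVE, n_properties=3
            ),
            150: PlantedSite(frozenset({Method.SLAC, Method.FEL}), Sign.POSITIVE),
            60: PlantedSite(dm_neg, Sign.NEGATIVE),
        },
        pdb_offset=17,
        pdb_deletions=(),
    )


def random_spec(seed: int) -> FixtureSpec:
    """A randomized plant for property-style pipeline tests."""
    rng = np.random.default_rng(seed)
    n_sites = int(rng.integers(120, 400))
    n_sequences = int(rng.integers(8, 40))
    n_planted = int(rng.integers(3, 10))
    sites = rng.choice(np.arange(5, n_sites - 4), size=n_planted, replace=False)
    dm = [Method.SLAC, Method.FEL, Method.REL, Method.MEME, Method.FUBAR]
    planted: dict[int, PlantedSite] = {}
    for i, site in enumerate(sorted(int(s) for s in sites)):
        if i == 0:
            # always at least one site detected by everything
            methods = set(dm) | {Method.PAML_M8, Method.TREESAAP}
            sign = Sign.POSITIVE
        else:
            k = int(rng.integers(1, 8))
            pool = dm + [Method.PAML_M8, Method.TREESAAP]
            idx = rng.choice(len(pool), size=min(k, len(pool)), replace=False)
            methods = {pool[int(i)] for i in idx}
            sign = Sign.POSITIVE
            if Method.MEME not in methods and Method.PAML_M8 not in methods and rng.random() < 0.2:
                sign = Sign.NEGATIVE
        n_props = int(rng.integers(1, 9)) if Method.TREESAAP in methods else 0
        planted[site] = PlantedSite(frozenset(methods), sign, n_props)
    offset = int(rng.integers(1, 40))
    return FixtureSpec(
        seed=seed, n_sites=n_sites, n_sequences=n_sequences,
        planted_sites=planted, pdb_offset=offset,
    )


# ---------------------------------------------------------------------------
# codeml result files

_MODEL_HEADERS = {
    "M0": "Model 0: one-ratio",
    "M1a": "Model 1: NearlyNeutral (2 categories)",
    "M2a": "Model 2: PositiveSelection (3 categories)",
    "M3": "Model 3: discrete (3 categories)",
    "M7": "Model 7: beta (10 categories)",
    "M8": "Model 8: beta&w>1 (11 categories)",
}
# free parameters beyond branch lengths and kappa, per site model
_EXTRA_NP = {"M0": 1, "M1a": 3, "M2a": 5, "M3": 5, "M7": 2, "M8": 4}
_DEFAULT_LNL = {
    "M0": -2400.123456, "M3": -2380.123456,
    "M1a": -2360.5, "M2a": -2350.5,
    "M7": -2358.0, "M8": -2345.6789,
}


def _default_params(model_id: str, kappa: float = 2.34567) -> dict[str, float]:
    base = {"kappa": kappa}
    if model_id == "M0":
        base.update(w=0.35)
    elif model_id == "M1a":
        base.update(p0=0.8, p1=0.2, w0=0.1, w1=1.0)
    elif model_id == "M2a":
        base.update(p0=0.75, p1=0.15, p2=0.10, w0=0.1, w1=1.0, w2=2.8)
    elif model_id == "M3":
        base.update(p0=0.6, p1=0.3, p2=0.1, w0=0.05, w1=0.5, w2=1.9)
    elif model_id == "M7":
        base.update(p=0.4, q=1.2)
    elif model_id == "M8":
        base.update(p0=0.9, p1=0.1, p=0.4, q=1.2, w=2.5)
    return base


def write_codeml_fixture(
    spec: FixtureSpec,
    model_id: str,
    path: str | Path,
    lnL: float | None = None,
    np_: int | None = None,
    beb_sites: list[tuple[int, str, float]] | None = None,
    params: dict[str, float] | None = None,
) -> Path:
    """Write one codeml main-result file in the PAML 4.x layout.

    BEB rows default to the spec's plant for the model (plus a few seeded
    sub-threshold rows); passing explicit ``beb_sites`` for a null model is an
    error, since codeml prints the BEB block only for M2a/M8.
    """
    if model_id not in _MODEL_HEADERS:
        raise ValueError(f"unknown site model {model_id!r}")
    is_alt = model_id in ("M2a", "M8")
    if beb_sites and not is_alt:
        raise ValueError(f"cannot plant BEB sites on null model {model_id}")

    rng = spec.rng(f"codeml/{model_id}")
    ntime = 2 * spec.n_sequences - 3
    np_value = np_ if np_ is not None else ntime + 1 + _EXTRA_NP[model_id]
    lnl_value = lnL if lnL is not None else _DEFAULT_LNL[model_id]
    param_values = params if params is not None else _default_params(model_id)

    if beb_sites is None and is_alt:
        method = Method.PAML_M8 if model_id == "M8" else Method.PAML_M2A
        planted = spec.sites_for(method)
        beb_sites = [
            (s, _RESIDUES[int(rng.integers(len(_RESIDUES)))],
             round(float(rng.uniform(0.96, 0.999)), 3))
            for s in planted
        ]
        # sub-threshold BEB rows at unplanted sites (codeml lists P > 0.5)
        free = sorted(set(range(1, spec.n_sites + 1)) - set(spec.planted_sites))
        decoys = rng.choice(free, size=min(3, len(free)), replace=False)
        for s in sorted(int(d) for d in decoys):
            beb_sites.append(
                (s, _RESIDUES[int(rng.integers(len(_RESIDUES)))],
                 round(float(rng.uniform(0.55, 0.85)), 3))
            )
        beb_sites.sort()

    lines = [
        "CODONML (in paml version 4.9j, February 2020)",
        "",
        _MODEL_HEADERS[model_id],
        "",
        f"lnL(ntime: {ntime}  np: {np_value}): {lnl_value:.6f}      +0.000000",
        "",
    ]
    if "kappa" in param_values:
        lines.append(f"kappa (ts/tv) =  {param_values['kappa']:.5f}")
        lines.append("")
    other = {k: v for k, v in param_values.items() if k != "kappa"}
    if other:
        lines.append(f"Parameters in {model_id}:")
        lines.append("  " + "  ".join(f"{k} = {v:.5f}" for k, v in other.items()))
        lines.append("")
    if is_alt and beb_sites is not None:
        lines += [
            "Bayes Empirical Bayes (BEB) analysis (Yang, Wong & Nielsen 2005. "
            "Mol. Biol. Evol. 22:1107-1118)",
            "Positively selected sites (*: P>95%; **: P>99%)",
            "(amino acids refer to 1st sequence: ref)",
            "",
            "            Pr(w>1)     post mean +- SE for w",
            "",
        ]
        for site, res, pp in beb_sites:
            stars = "**" if pp > 0.99 else ("*" if pp > 0.95 else "")
            omega = 1.0 + pp * 2.0
            lines.append(f"   {site:>4} {res}      {pp:.3f}{stars}       {omega:.3f} +- 0.512")
        lines.append("")
    path = Path(path)
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


# ---------------------------------------------------------------------------
# Datamonkey method tables

def write_datamonkey_fixture(spec: FixtureSpec, method: Method | str, path: str | Path) -> Path:
    """Write one per-method site table in the frozen built-in dialect.

    Planted sites get statistics passing the default cutoff for their sign;
    every other site fails with a margin of at least twice the cutoff
    distance, so default-threshold filtering recovers the plant exactly.
    """
    method = Method(method)
    rng = spec.rng(f"datamonkey/{method.value}")
    rows: list[str] = []

    def plant_at(site: int) -> PlantedSite | None:
        p = spec.planted_sites.get(site)
        return p if p is not None and method in p.methods else None

    if method is Method.SLAC:
        header = "Site,dN-dS,P-value"
        for site in range(1, spec.n_sites + 1):
            p = plant_at(site)
            if p is not None:
                pval = rng.uniform(0.005, 0.09)
                diff = rng.uniform(0.5, 3.0) * (1 if p.sign is Sign.POSITIVE else -1)
            else:
                pval = rng.uniform(0.3, 0.95)
                diff = rng.uniform(-1.0, 1.0)
            rows.append(f"{site},{diff:.4f},{pval:.4f}")
    elif method is Method.FEL:
        header = "Site,alpha,beta,P-value"
        for site in range(1, spec.n_sites + 1):
            p = plant_at(site)
            lo, hi = rng.uniform(0.0, 0.5), None
            if p is not None:
                pval = rng.uniform(0.005, 0.09)
                hi = lo + rng.uniform(0.5, 2.0)
                a, b = (lo, hi) if p.sign is Sign.POSITIVE else (hi, lo)
            else:
                pval = rng.uniform(0.3, 0.95)
                a, b = lo, max(0.0, lo + rng.uniform(-0.4, 0.4))
            rows.append(f"{site},{a:.4f},{b:.4f},{pval:.4f}")
    elif method is Method.MEME:
        header = "Site,p-value"
        for site in range(1, spec.n_sites + 1):
            p = plant_at(site)
            pval = rng.uniform(0.005, 0.09) if p is not None else rng.uniform(0.3, 0.95)
            rows.append(f"{site},{pval:.4f}")
    elif method is Method.REL:
        header = "Site,Bayes Factor [omega>1],Bayes Factor [omega<1]"
        for site in range(1, spec.n_sites + 1):
            p = plant_at(site)
            bf_pos = float(rng.uniform(0.0, 20.0))
            bf_neg = float(rng.uniform(0.0, 20.0))
            if p is not None:
                if p.sign is Sign.POSITIVE:
                    bf_pos = rng.uniform(55.0, 800.0)
                else:
                    bf_neg = rng.uniform(55.0, 800.0)
            rows.append(f"{site},{bf_pos:.2f},{bf_neg:.2f}")
    elif method is Method.FUBAR:
        header = "Site,alpha,beta,Prob[alpha<beta],Prob[alpha>beta]"
        for site in range(1, spec.n_sites + 1):
            p = plant_at(site)
            a = rng.uniform(0.1, 1.0)
            if p is not None:
                if p.sign is Sign.POSITIVE:
                    b = a + rng.uniform(0.5, 2.0)
                    post_pos, post_neg = rng.uniform(0.91, 0.995), rng.uniform(0.0, 0.05)
                else:
                    b = max(0.0, a - rng.uniform(0.05, 0.09))
                    post_pos, post_neg = rng.uniform(0.0, 0.05), rng.uniform(0.91, 0.995)
            else:
                b = a + rng.uniform(-0.3, 0.3)
                post_pos, post_neg = rng.uniform(0.05, 0.45), rng.uniform(0.05, 0.45)
            rows.append(f"{site},{a:.4f},{b:.4f},{post_pos:.4f},{post_neg:.4f}")
    else:
        raise ValueError(f"{method.value} is not a Datamonkey site method")

    path = Path(path)
    path.write_text(header + "\n" + "\n".join(rows) + "\n", encoding="utf-8")
    return path


# ---------------------------------------------------------------------------
# TreeSAAP result trees

def _safe_filename(name: str) -> str:
    return re.sub(r"[^A-Za-z0-9]+", "_", name).strip("_")


def write_treesaap_fixture(
    spec: FixtureSpec, root_dir: str | Path, window: int = 20, step: int = 10
) -> Path:
    """Write an ``Evpthwy/`` + ``Substs/`` result tree.

    Each planted TreeSAAP site with ``n_properties`` = k receives qualifying
    per-site records (category 7/8, |Z| well above 3.09) for k seeded distinct
    properties, plus decoy records that never qualify (sub-threshold Z or
    category below 7); the window series are kept consistent, lighting up the
    category-8 Z of every window covering a planted codon.
    """
    root = Path(root_dir)
    substs_dir = root / "Substs"
    evp_dir = root / "Evpthwy"
    substs_dir.mkdir(parents=True, exist_ok=True)
    evp_dir.mkdir(parents=True, exist_ok=True)
    registry = DEFAULT_REGISTRY
    rng = spec.rng("treesaap")

    # assign k distinct properties to every planted TreeSAAP codon
    assignment: dict[int, list[str]] = {}
    for site in sorted(spec.planted_sites):
        plant = spec.planted_sites[site]
        if Method.TREESAAP not in plant.methods:
            continue
        idx = rng.choice(len(registry.names), size=plant.n_properties, replace=False)
        assignment[site] = [registry.names[int(i)] for i in sorted(idx)]

    by_property: dict[str, list[tuple[int, int, float, str]]] = {}
    for site, props in assignment.items():
        sign = spec.planted_sites[site].sign
        for prop in props:
            cat = int(rng.choice([7, 8]))
            z = float(rng.uniform(3.3, 6.0))
            if sign is Sign.NEGATIVE:
                z = -z
            branch = f"br{int(rng.integers(1, 2 * spec.n_sequences))}"
            by_property.setdefault(prop, []).append((site, cat, z, branch))

    # decoy records: never qualify (low |Z| in 7/8, or high Z in category <= 6)
    free_sites = sorted(set(range(1, spec.n_sites + 1)) - set(spec.planted_sites))
    for prop in registry.names[:8]:
        for _ in range(3):
            site = int(rng.choice(free_sites))
            if rng.random() < 0.5:
                cat, z = int(rng.choice([7, 8])), float(rng.uniform(0.0, 2.5))
            else:
                cat, z = int(rng.integers(1, 7)), float(rng.uniform(3.2, 6.0))
            by_property.setdefault(prop, []).append((site, cat, z, "br1"))

    for prop in sorted(by_property):
        lines = [f"# property: {prop}", "codon\tcategory\tz_score\tbranch"]
        for codon, cat, z, branch in sorted(by_property[prop]):
            lines.append(f"{codon}\t{cat}\t{z:.3f}\t{branch}")
        (substs_dir / f"{_safe_filename(prop)}.substs.tsv").write_text(
            "\n".join(lines) + "\n", encoding="utf-8"
        )

    # sliding-window series consistent with the per-site plants
    windows = [
        (start, min(start + window - 1, spec.n_sites))
        for start in range(1, spec.n_sites - window + 2, step)
    ]
    for prop in sorted(by_property):
        planted_codons = {
            site for site, props in assignment.items() if prop in props
        }
        lines = [f"# property: {prop}",
                 "from\tto\t" + "\t".join(f"z_cat{c}" for c in range(1, 9))]
        for lo, hi in windows:
            z = rng.uniform(-2.0, 2.0, size=8)
            covered = {s for s in planted_codons if lo <= s <= hi}
            if covered:
                sign = spec.planted_sites[next(iter(covered))].sign
                zval = float(rng.uniform(3.3, 5.5))
                z[7] = zval if sign is Sign.POSITIVE else -zval
            lines.append(f"{lo}\t{hi}\t" + "\t".join(f"{v:.3f}" for v in z))
        (evp_dir / f"{_safe_filename(prop)}.evpthwy.tsv").write_text(
            "\n".join(lines) + "\n", encoding="utf-8"
        )
    return root


# ---------------------------------------------------------------------------
# codon alignment, tree and toy PDB

def build_alignment_records(spec: FixtureSpec) -> list[tuple[str, str]]:
    """Seeded gapless codon alignment; the first sequence ('ref') is the
    reference whose translation feeds the structure mapping."""
    rng = spec.rng("alignment")
    ref_codons = [
        _SENSE_CODONS[int(i)] for i in rng.integers(len(_SENSE_CODONS), size=spec.n_sites)
    ]
    records = [("ref", "".join(ref_codons))]
    for j in range(1, spec.n_sequences):
        codons = list(ref_codons)
        n_mut = max(1, spec.n_sites // 10)
        for pos in rng.choice(spec.n_sites, size=n_mut, replace=False):
            codons[int(pos)] = _SENSE_CODONS[int(rng.integers(len(_SENSE_CODONS)))]
        records.append((f"seq{j}", "".join(codons)))
    return records


def write_alignment_fixture(spec: FixtureSpec, path: str | Path, format: str = "fasta") -> Path:
    from .seqmap import CodonAlignment, write_alignment

    aln = CodonAlignment(records=build_alignment_records(spec))
    path = Path(path)
    write_alignment(aln, path, format=format)
    return path


def write_tree_fixture(spec: FixtureSpec, path: str | Path) -> Path:
    """A caterpillar Newick tree over the alignment's sequence ids."""
    ids = ["ref"] + [f"seq{j}" for j in range(1, spec.n_sequences)]
    tree = ids[0]
    for name in ids[1:]:
        tree = f"({tree}:0.1,{name}:0.1)"
    path = Path(path)
    path.write_text(tree + ";\n", encoding="utf-8")
    return path


_1TO3 = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR",
}


def write_pdb_fixture(
    spec: FixtureSpec, sequence: str, path: str | Path, chain_id: str | None = None
) -> Path:
    """Minimal single-chain PDB: one CA atom per residue.

    Residue i of ``sequence`` (1-based) is numbered ``pdb_offset + i - 1``;
    positions listed in ``spec.pdb_deletions`` are omitted from the
    coordinates, emulating unresolved residues.
    """
    chain = chain_id or spec.chain_id
    deletions = set(spec.pdb_deletions)
    lines = ["HEADER    SYNTHETIC TOY STRUCTURE"]
    serial = 0
    for i, aa in enumerate(sequence, start=1):
        if i in deletions:
            continue
        serial += 1
        resnum = spec.pdb_offset + i - 1
        resname = _1TO3.get(aa.upper(), "GLY")
        x = 3.8 * serial
        lines.append(
            f"ATOM  {serial:>5}  CA  {resname} {chain}{resnum:>4}    "
            f"{x:8.3f}{0.0:8.3f}{0.0:8.3f}  1.00  0.00           C"
        )
    lines.append("TER")
    lines.append("END")
    path = Path(path)
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def write_workspace(spec: FixtureSpec, out_dir: str | Path) -> dict[str, Path]:
    """Emit a complete demo workspace: every input family plus the alignment,
    tree and structure the mapping stage needs.  Returns the path map."""
    from .seqmap import CodonAlignment, translate_reference

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for model in ("M0", "M1a", "M2a", "M3", "M7", "M8"):
        paths[f"codeml_{model}"] = write_codeml_fixture(
            spec, model, out / f"codeml_{model}.txt"
        )
    for method in (Method.SLAC, Method.FEL, Method.REL, Method.MEME, Method.FUBAR):
        paths[f"datamonkey_{method.value}"] = write_datamonkey_fixture(
            spec, method, out / f"{method.value.lower()}.csv"
        )
    paths["treesaap"] = write_treesaap_fixture(spec, out / "treesaap")
    paths["alignment"] = write_alignment_fixture(spec, out / "alignment.fasta")
    paths["alignment_phylip"] = write_alignment_fixture(
        spec, out / "alignment.phy", format="phylip"
    )
    paths["tree"] = write_tree_fixture(spec, out / "tree.nwk")
    aln = CodonAlignment(records=build_alignment_records(spec))
    protein = translate_reference(aln, "ref")
    paths["pdb"] = write_pdb_fixture(spec, protein, out / "structure.pdb")
    return paths
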