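"""Multi-level agreement between diplotype call columns.

Callers print diplotypes in slightly different dialects: with or without
suballeles (``*2`` vs ``*2.011``), with ``+extra`` variant annotations
(``*1.002 + rs4986894``), and — for callers that emit ranked output — a
bracketed alternative (``*1/*4 (*1/*17)``).  This module parses such cells
into ranked lists of structured diplotypes and scores agreement at three
levels: ``minor_exact`` (full tokens including extras), ``major``
(suballeles and extras stripped), and ``phenotype`` (printed metabolizer
categories).  A malformed cell is flagged and counted as a disagreement,
never dropped.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "AlleleToken",
    "ParsedDiplotype",
    "DiplotypeString",
    "ConcordanceResult",
    "parse_cell",
    "normalize_diplotype",
    "agreement",
    "phenotype_concordance",
    "load_table2_calls",
]

LEVELS = ("minor_exact", "major", "phenotype")

_STAR_RE = re.compile(r"^\*(\d+)(?:\.(\d+))?")
_EXTRA_RE = re.compile(r"([+\-–−])\s*([A-Za-z0-9.>_]+)")
_PHENO_RE = re.compile(r"^[A-Z]{2}$")


@dataclass(frozen=True)
class AlleleToken:
    major: str
    suballele: str | None
    extras: tuple[tuple[str, str], ...]  # (sign, identifier), sign in {+,-}

    def minor_token(self) -> str:
        name = self.suballele or self.major
        return name + "".join(f"{s}{i}" for s, i in sorted(self.extras))


@dataclass(frozen=True)
class ParsedDiplotype:
    alleles: tuple[AlleleToken, AlleleToken]


@dataclass(frozen=True)
class DiplotypeString:
    raw: str
    ranked: tuple[ParsedDiplotype, ...]  # first-listed call, then alternates
    phenotype: str | None
    well_formed: bool


def _parse_allele(tok: str) -> AlleleToken:
    tok = tok.strip()
    m = _STAR_RE.match(tok)
    if not m:
        raise ValueError(f"allele token does not start with a star allele: {tok!r}")
    major = f"*{m.group(1)}"
    suballele = f"*{m.group(1)}.{m.group(2)}" if m.group(2) else None
    rest = tok[m.end():]
    extras = []
    consumed = 0
    for em in _EXTRA_RE.finditer(rest):
        sign = "+" if em.group(1) == "+" else "-"
        extras.append((sign, em.group(2)))
        consumed = em.end()
    if rest[consumed:].strip():
        raise ValueError(f"trailing junk in allele token: {tok!r}")
    return AlleleToken(major=major, suballele=suballele, extras=tuple(extras))


def _parse_diplotype(text: str) -> ParsedDiplotype:
    halves = text.split("/")
    if len(halves) != 2:
        raise ValueError(f"expected exactly one '/' in diplotype: {text!r}")
    return ParsedDiplotype(alleles=(_parse_allele(halves[0]), _parse_allele(halves[1])))


def parse_cell(raw: str) -> DiplotypeString:
    """Parse one table cell into ranked diplotypes plus optional phenotype.

    Trailing parenthesized groups are either a phenotype category (``(NM)``)
    or a bracketed alternative diplotype (``(*1/*17)``).
    """
    phenotype: str | None = None
    alternates: list[str] = []
    body = raw.strip()
    try:
        while True:
            m = re.search(r"\(([^()]*)\)\s*$", body)
            if not m:
                break
            inner = m.group(1).strip()
            if "/" in inner:
                alternates.insert(0, inner)
            elif _PHENO_RE.match(inner):
                phenotype = inner
            else:
                raise ValueError(f"unrecognized parenthesized group {inner!r}")
            body = body[: m.start()].strip()
        ranked = [_parse_diplotype(body)] + [_parse_diplotype(a) for a in alternates]
        return DiplotypeString(raw=raw, ranked=tuple(ranked), phenotype=phenotype, well_formed=True)
    except ValueError:
        return DiplotypeString(raw=raw, ranked=(), phenotype=phenotype, well_formed=False)


def normalize_diplotype(d: ParsedDiplotype, level: str) -> tuple[str, str]:
    """Canonical order-insensitive token pair at the given level."""
    if level == "minor_exact":
        toks = sorted(a.minor_token() for a in d.alleles)
    elif level == "major":
        toks = sorted(a.major for a in d.alleles)
    else:
        raise ValueError(f"normalize_diplotype does not handle level {level!r}")
    return (toks[0], toks[1])


@dataclass(frozen=True)
class ConcordanceResult:
    label: str
    level: str
    n_total: int
    n_agree: int
    disagreeing: tuple[str, ...]

    @property
    def percent(self) -> float:
        return 100.0 * self.n_agree / self.n_total if self.n_total else float("nan")


def _as_mapping(column) -> dict[str, str]:
    if isinstance(column, Mapping):
        return dict(column)
    if isinstance(column, pd.Series):
        return {str(k): str(v) for k, v in column.items()}
    raise TypeError("call column must be a mapping or pandas Series keyed by sample id")


def agreement(
    reference,
    tool,
    level: str = "major",
    any_listed: bool = False,
    label: str = "",
) -> ConcordanceResult:
    """Score agreement between two call columns aligned by sample id.

    The reference column contributes its first-listed diplotype; the tool
    column matches on its first-listed diplotype, or on any diplotype in
    its ranked list when ``any_listed`` is true.
    """
    ref = _as_mapping(reference)
    tol = _as_mapping(tool)
    if set(ref) != set(tol):
        raise ValueError("columns are not aligned by sample id")
    if len(ref) != len(reference):
        raise ValueError("duplicate sample ids")
    disagree: list[str] = []
    for sid in ref:
        r = parse_cell(ref[sid])
        t = parse_cell(tol[sid])
        if not (r.well_formed and t.well_formed and r.ranked and t.ranked):
            disagree.append(sid)
            continue
        r_tok = normalize_diplotype(r.ranked[0], level)
        t_toks = [normalize_diplotype(d, level) for d in (t.ranked if any_listed else t.ranked[:1])]
        if r_tok not in t_toks:
            disagree.append(sid)
    n = len(ref)
    return ConcordanceResult(
        label=label,
        level=level if not any_listed else f"{level}_any_listed",
        n_total=n,
        n_agree=n - len(disagree),
        disagreeing=tuple(sorted(disagree, key=str)),
    )


def phenotype_concordance(reference, tool, label: str = "") -> ConcordanceResult:
    """Agreement on the printed phenotype categories of two call columns."""
    ref = _as_mapping(reference)
    tol = _as_mapping(tool)
    if set(ref) != set(tol):
        raise ValueError("columns are not aligned by sample id")
    disagree = []
    for sid in ref:
        pr = parse_cell(ref[sid]).phenotype
        pt = parse_cell(tol[sid]).phenotype
        if pr is None or pt is None or pr != pt:
            disagree.append(sid)
    n = len(ref)
    return ConcordanceResult(
        label=label, level="phenotype", n_total=n, n_agree=n - len(disagree),
        disagreeing=tuple(sorted(disagree, key=str)),
    )


def load_table2_calls(path: str | Path | None = None) -> pd.DataFrame:
    """The bundled 37-sample published call table (manual + three tools),
    indexed by sample id with columns manual/aldy/pharmaku/pharmcat."""
    if path is None:
        ref = resources.files("phasestar.data").joinpath("table2_calls.tsv")
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t", comment="#", dtype=str)
    else:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    return df.set_index("sample")
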