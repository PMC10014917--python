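"""Star-allele nomenclature tables: data model, validation and I/O.

A pharmacogene haplotype ("star allele", e.g. CYP2C19*2) is defined by the
set of variants it carries.  Each *major* allele (``*2``) groups a family of
*suballeles* (``*2.001``, ``*2.011`` ...) that share the major's *core*
variants and differ in additional, usually non-functional, variants.  This
module models such PharmVar-style definition tables and reads/writes them in
a simple long-format TSV (one row per suballele-variant pair) and a JSON
mirror.

The bundled CYP2C19 table (``data/cyp2c19_alleles.tsv``) encodes the
clinically documented relationships for the suballeles used throughout this
package; positions that only serve to distinguish suballeles from one
another and have no published identity here carry an ``SYN_``-prefixed rsid
marking them as synthetic placeholders.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "VariantKey",
    "StarAlleleDefinition",
    "AlleleDefinitionTable",
    "AlleleTableError",
    "load_allele_table",
    "write_allele_table",
    "bundled_cyp2c19_table",
    "suballeles_of",
]

_BASES = set("ACGT")

FUNCTION_CLASSES = frozenset(
    {"normal", "decreased", "no_function", "increased", "unknown"}
)


class AlleleTableError(ValueError):
    """Raised for malformed or invariant-violating allele definition input."""


@dataclass(frozen=True, order=True)
class VariantKey:
    """A genomic variant identified by (chrom, pos, ref, alt).

    ``pos`` is the 1-based position on the given chromosome (GRCh38
    throughout this package).  The optional rsid is decorative: it does not
    participate in equality or ordering.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    rsid: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise AlleleTableError(f"variant position must be >= 1, got {self.pos}")
        for label, seq in (("ref", self.ref), ("alt", self.alt)):
            if not seq or not set(seq) <= _BASES:
                raise AlleleTableError(
                    f"{label} allele {seq!r} is not a non-empty uppercase ACGT string"
                )
        if self.ref == self.alt:
            raise AlleleTableError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")

    @property
    def gdot(self) -> str:
        """HGVS-like genomic shorthand, e.g. ``g.94781859G>A``."""
        return f"g.{self.pos}{self.ref}>{self.alt}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


@dataclass(frozen=True)
class StarAlleleDefinition:
    gene: str
    major: str
    suballele: str
    defining_variants: frozenset[VariantKey]
    core_variants: frozenset[VariantKey]
    function: str

    def __post_init__(self) -> None:
        if not self.suballele.startswith(self.major):
            raise AlleleTableError(
                f"suballele {self.suballele} does not extend major {self.major}"
            )
        if not self.core_variants <= self.defining_variants:
            raise AlleleTableError(
                f"{self.suballele}: core variants not a subset of defining variants"
            )
        if self.function not in FUNCTION_CLASSES:
            raise AlleleTableError(
                f"{self.suballele}: unknown function class {self.function!r}"
            )


class AlleleDefinitionTable:
    """A validated collection of suballele definitions for one gene."""

    def __init__(
        self,
        gene: str,
        alleles: Iterable[StarAlleleDefinition],
        reference_allele: str,
        strict: bool = True,
    ) -> None:
        self.gene = gene
        self.alleles: dict[str, StarAlleleDefinition] = {}
        for a in alleles:
            if a.suballele in self.alleles:
                raise AlleleTableError(f"duplicate suballele name {a.suballele}")
            if a.gene != gene:
                raise AlleleTableError(
                    f"{a.suballele}: gene {a.gene} != table gene {gene}"
                )
            self.alleles[a.suballele] = a
        if reference_allele not in self.alleles:
            raise AlleleTableError(
                f"reference allele {reference_allele} not among defined suballeles"
            )
        self.reference_allele = reference_allele
        self._validate(strict=strict)

    # -- validation -----------------------------------------------------

    def _validate(self, strict: bool) -> None:
        by_major: dict[str, list[StarAlleleDefinition]] = {}
        for a in self.alleles.values():
            by_major.setdefault(a.major, []).append(a)
        for major, members in by_major.items():
            cores = {a.core_variants for a in members}
            if len(cores) > 1:
                names = sorted(a.suballele for a in members)
                raise AlleleTableError(
                    f"suballeles of {major} disagree on core variants: {names}"
                )
        if strict:
            seen: dict[frozenset[VariantKey], str] = {}
            for name in sorted(self.alleles):
                ds = self.alleles[name].defining_variants
                if ds in seen:
                    raise AlleleTableError(
                        f"non-unique defining set: {name} duplicates {seen[ds]}"
                    )
                seen[ds] = name

    # -- accessors ------------------------------------------------------

    @property
    def variant_universe(self) -> frozenset[VariantKey]:
        out: set[VariantKey] = set()
        for a in self.alleles.values():
            out |= a.defining_variants
        return frozenset(out)

    def majors(self) -> list[str]:
        return sorted({a.major for a in self.alleles.values()}, key=_star_sort_key)

    def function_of(self, major: str) -> str:
        members = [a for a in self.alleles.values() if a.major == major]
        if not members:
            raise KeyError(f"unknown major allele {major}")
        functions = {a.function for a in members}
        if len(functions) > 1:
            raise AlleleTableError(
                f"suballeles of {major} disagree on function: {sorted(functions)}"
            )
        return members[0].function

    def __iter__(self):
        return iter(self.alleles.values())

    def __len__(self) -> int:
        return len(self.alleles)

    def __getitem__(self, name: str) -> StarAlleleDefinition:
        return self.alleles[name]

    def __contains__(self, name: str) -> bool:
        return name in self.alleles


def _star_sort_key(name: str) -> tuple:
    # "*2.011" -> (2, 11); "*17" -> (17, -1); non-numeric parts sort last
    body = name.lstrip("*")
    parts = body.split(".")
    try:
        majnum = int(parts[0])
    except ValueError:
        return (1 << 30, body)
    minor = int(parts[1]) if len(parts) > 1 and parts[1].isdigit() else -1
    return (majnum, minor)


def suballeles_of(table: AlleleDefinitionTable, major: str) -> set[StarAlleleDefinition]:
    """All suballeles of ``major``; raises KeyError for an unknown major."""
    out = {a for a in table if a.major == major}
    if not out:
        raise KeyError(f"unknown major allele {major}")
    return out


# ----------------------------------------------------------------------
# I/O
# ----------------------------------------------------------------------

_COLUMNS = ["gene", "suballele", "major", "function", "chrom", "pos", "ref", "alt", "rsid", "is_core"]


def load_allele_table(path: str | Path, format: str | None = None, strict: bool = True) -> AlleleDefinitionTable:
    """Load an allele-definition table from TSV or JSON.

    The TSV dialect is long-format: one row per (suballele, variant) pair
    with columns ``gene suballele major function chrom pos ref alt rsid
    is_core``; an allele with no defining variants is declared by a single
    row with the variant columns empty.  A comment line
    ``#reference_allele=<name>`` names the reference; absent that, the
    unique allele with an empty defining set is taken as reference.
    """
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "tsv"
    if format == "json":
        return _load_json(path, strict=strict)
    if format == "tsv":
        return _load_tsv(path, strict=strict)
    raise ValueError(f"unknown format {format!r}")


def _load_tsv(path: Path, strict: bool) -> AlleleDefinitionTable:
    reference: str | None = None
    rows: list[tuple[int, list[str]]] = []
    header: list[str] | None = None
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                if line.startswith("#reference_allele="):
                    reference = line.split("=", 1)[1].strip()
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                if header != _COLUMNS:
                    raise AlleleTableError(
                        f"{path}:{lineno}: bad header, expected {_COLUMNS}, got {header}"
                    )
                continue
            if len(fields) != len(_COLUMNS):
                raise AlleleTableError(
                    f"{path}:{lineno}: expected {len(_COLUMNS)} fields, got {len(fields)}"
                )
            rows.append((lineno, fields))
    if header is None:
        raise AlleleTableError(f"{path}: missing header")
    return _assemble(rows, reference, strict=strict, origin=str(path))


def _assemble(
    rows: list[tuple[int, list[str]]],
    reference: str | None,
    strict: bool,
    origin: str,
) -> AlleleDefinitionTable:
    genes: set[str] = set()
    meta: dict[str, tuple[str, str]] = {}  # suballele -> (major, function)
    defining: dict[str, set[VariantKey]] = {}
    core: dict[str, set[VariantKey]] = {}
    for lineno, f in rows:
        rec = dict(zip(_COLUMNS, f))
        genes.add(rec["gene"])
        sub = rec["suballele"]
        prev = meta.get(sub)
        cur = (rec["major"], rec["function"])
        if prev is not None and prev != cur:
            raise AlleleTableError(
                f"{origin}:{lineno}: inconsistent major/function for {sub}"
            )
        meta[sub] = cur
        defining.setdefault(sub, set())
        core.setdefault(sub, set())
        if rec["pos"].strip() == "":
            continue  # allele-level row
        try:
            var = VariantKey(
                chrom=rec["chrom"],
                pos=int(rec["pos"]),
                ref=rec["ref"],
                alt=rec["alt"],
                rsid=rec["rsid"] or None,
            )
        except (ValueError, AlleleTableError) as exc:
            raise AlleleTableError(f"{origin}:{lineno}: {exc}") from exc
        defining[sub].add(var)
        if rec["is_core"].strip() in {"1", "true", "True"}:
            core[sub].add(var)
    if len(genes) != 1:
        raise AlleleTableError(f"{origin}: expected exactly one gene, got {sorted(genes)}")
    gene = genes.pop()
    alleles = [
        StarAlleleDefinition(
            gene=gene,
            major=meta[sub][0],
            suballele=sub,
            defining_variants=frozenset(defining[sub]),
            core_variants=frozenset(core[sub]),
            function=meta[sub][1],
        )
        for sub in meta
    ]
    if reference is None:
        empties = [a.suballele for a in alleles if not a.defining_variants]
        if len(empties) != 1:
            raise AlleleTableError(
                f"{origin}: reference allele not declared and not inferable "
                f"(alleles with empty defining sets: {empties})"
            )
        reference = empties[0]
    return AlleleDefinitionTable(gene, alleles, reference, strict=strict)


def _load_json(path: Path, strict: bool) -> AlleleDefinitionTable:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    alleles = []
    for rec in doc["alleles"]:
        variants = []
        cores = []
        for v in rec.get("variants", []):
            var = VariantKey(
                chrom=v["chrom"], pos=int(v["pos"]), ref=v["ref"], alt=v["alt"],
                rsid=v.get("rsid"),
            )
            variants.append(var)
            if v.get("is_core"):
                cores.append(var)
        alleles.append(
            StarAlleleDefinition(
                gene=doc["gene"],
                major=rec["major"],
                suballele=rec["suballele"],
                defining_variants=frozenset(variants),
                core_variants=frozenset(cores),
                function=rec["function"],
            )
        )
    return AlleleDefinitionTable(doc["gene"], alleles, doc["reference_allele"], strict=strict)


def write_allele_table(table: AlleleDefinitionTable, path: str | Path, format: str | None = None) -> None:
    """Write a table in canonical order (suballele, then position)."""
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "tsv"
    names = sorted(table.alleles, key=_star_sort_key)
    if format == "tsv":
        lines = [f"#reference_allele={table.reference_allele}", "\t".join(_COLUMNS)]
        for name in names:
            a = table[name]
            variants = sorted(a.defining_variants)
            if not variants:
                lines.append(
                    "\t".join([table.gene, a.suballele, a.major, a.function, "", "", "", "", "", ""])
                )
                continue
            for v in variants:
                lines.append(
                    "\t".join(
                        [
                            table.gene, a.suballele, a.major, a.function,
                            v.chrom, str(v.pos), v.ref, v.alt, v.rsid or "",
                            "1" if v in a.core_variants else "0",
                        ]
                    )
                )
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
    elif format == "json":
        doc = {
            "gene": table.gene,
            "reference_allele": table.reference_allele,
            "alleles": [
                {
                    "suballele": table[name].suballele,
                    "major": table[name].major,
                    "function": table[name].function,
                    "variants": [
                        {
                            "chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
                            "rsid": v.rsid, "is_core": v in table[name].core_variants,
                        }
                        for v in sorted(table[name].defining_variants)
                    ],
                }
                for name in names
            ],
        }
        Path(path).write_text(json.dumps(doc, indent=1) + "\n", encoding="utf-8")
    else:
        raise ValueError(f"unknown format {format!r}")


def bundled_cyp2c19_table(strict: bool = True) -> AlleleDefinitionTable:
    """The package's simplified CYP2C19 definition table."""
    ref = resources.files("phasestar.data").joinpath("cyp2c19_alleles.tsv")
    with resources.as_file(ref) as p:
        return load_allele_table(p, strict=strict)
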