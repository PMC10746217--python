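"""Reference knowledge for the pipeline.

The registry holds three fixed catalogs:

* the flagellar query-gene catalog — 50 genes in six functional
  categories, of which 24 form the ancient structural core whose joint
  presence defines a flagellated genome;
* chemosensory F-class signatures (F1, F5, F7, F9, ACF) — component
  requirements, diagnostic auxiliaries, conserved operon order, and the
  cognate chemoreceptor heptad class of each;
* chemoreceptor heptad-length classes (24H ... 64H), used to bin the
  cytoplasmic signaling domain of MCPs by length in 7-residue heptads.

The built-in defaults can be serialized to, and reloaded from, a plain
sectioned TSV so that users can edit signatures (in particular the
F7/F9/ACF placeholders) without touching code.

Catalog counting note: the conventional query enumeration names more
symbols than the conventional count of 50 flagellar genes.  The
built-in catalog reaches 50 by (a) treating YvyC/FlaG as a single entry
with two names (homologs of the same filament-associated protein) and
(b) folding FlhX — a standalone homolog of the FlhB C-terminal domain
— into FlhB as an alias.  Readings that keep FlhX (or YvyC and FlaG)
as separate entries give a 51-gene catalog; either way the 24-gene
core is identical, and users preferring the split reading can load an
edited registry file.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "GeneDef",
    "FClassDef",
    "HClassDef",
    "Registry",
    "RegistryValidationError",
    "load_registry",
    "write_registry",
    "core_gene_set",
    "EFG_SYMBOLS",
    "AMBIGUOUS_EFG",
    "CHEMO_COMPONENTS",
    "COMPONENT_LETTERS",
]

CATEGORIES = ("fT3SS", "MS-ring", "motor", "rod", "hook_filament", "regulator")

#: The three rod/hook paralogs that homology alone cannot separate.
EFG_SYMBOLS = ("FlgE", "FlgF", "FlgG")

#: Label given to an FlgE/F/G candidate that neither gene-order cue resolves.
AMBIGUOUS_EFG = "FlgEFG_ambiguous"

#: Chemosensory component symbols recognized by the detector.
CHEMO_COMPONENTS = frozenset(
    {"CheA", "CheW", "CheB", "CheR", "CheC", "CheD", "CheX", "CheY", "MCP"}
)

#: Single-letter abbreviations used in operon order strings.
COMPONENT_LETTERS = {
    "CheA": "A",
    "CheA:W": "A:W",
    "CheW": "W",
    "CheB": "B",
    "CheR": "R",
    "CheC": "C",
    "CheD": "D",
    "CheX": "X",
    "CheY": "Y",
    "MCP": "M",
}


class RegistryValidationError(ValueError):
    """Raised when a registry violates a structural invariant."""


@dataclass(frozen=True)
class GeneDef:
    """One flagellar reference gene.

    Parameters
    ----------
    name : str
        Gene symbol, e.g. ``"FlgE"``.
    category : str
        One of the six functional categories in :data:`CATEGORIES`.
    is_core : bool
        Whether the gene belongs to the 24-gene ancient structural core.
    query_source : str
        Model organism the search query came from.
    aliases : tuple of str
        Alternative symbols (e.g. FlhO/FlhP for FlgF/FlgG in B. subtilis).
    """

    name: str
    category: str
    is_core: bool = False
    query_source: str = "S. Typhimurium"
    aliases: tuple[str, ...] = ()


@dataclass(frozen=True)
class FClassDef:
    """Signature of one chemosensory system class."""

    name: str
    required_components: frozenset[str]
    diagnostic_components: frozenset[str] = frozenset()
    order_pattern: str = ""
    kinase_variant: bool = False  # CheA carries an additional CheW domain
    cognate_h: str = ""


@dataclass(frozen=True)
class HClassDef:
    """A chemoreceptor signaling-domain length class, in 7-residue heptads."""

    label: str
    heptad_count: int
    tolerance: int = 2


# ---------------------------------------------------------------------------
# Built-in catalogs
# ---------------------------------------------------------------------------

_ST = "S. Typhimurium"
_BS = "B. subtilis"

# (name, category, core, source, aliases)
_GENE_TABLE: list[tuple[str, str, bool, str, tuple[str, ...]]] = [
    # flagellar type-III secretion system (10 entries; FlhX folded into FlhB)
    ("FlhA", "fT3SS", True, _ST, ()),
    ("FlhB", "fT3SS", True, _ST, ("FlhX",)),
    ("FlhE", "fT3SS", False, _ST, ()),
    ("FliP", "fT3SS", True, _ST, ()),
    ("FliQ", "fT3SS", True, _ST, ()),
    ("FliR", "fT3SS", True, _ST, ()),
    ("FliI", "fT3SS", True, _ST, ()),
    ("FliJ", "fT3SS", False, _ST, ()),
    ("FliH", "fT3SS", True, _ST, ()),
    ("FliO", "fT3SS", False, _ST, ()),
    # MS-ring (1)
    ("FliF", "MS-ring", True, _ST, ()),
    # motor associated (8)
    ("MotA", "motor", True, _ST, ()),
    ("MotB", "motor", True, _ST, ()),
    ("FliG", "motor", True, _ST, ()),
    ("FliM", "motor", True, _ST, ()),
    ("FliN", "motor", True, _ST, ()),
    ("FliY", "motor", False, _BS, ()),
    ("FliL", "motor", False, _ST, ()),
    ("SwrD", "motor", False, _BS, ()),
    # rod associated (10)
    ("FliE", "rod", True, _ST, ()),
    ("FlgB", "rod", True, _ST, ()),
    ("FlgC", "rod", True, _ST, ()),
    ("FlgF", "rod", True, _ST, ("FlhO",)),
    ("FlgG", "rod", True, _ST, ("FlhP",)),
    ("FlgH", "rod", False, _ST, ()),
    ("FlgI", "rod", False, _ST, ()),
    ("FlgA", "rod", False, _ST, ()),
    ("FlgJ", "rod", False, _ST, ()),
    ("CwlQ", "rod", False, _BS, ()),
    # hook and filament associated (11; YvyC/FlaG is one entry)
    ("FlgE", "hook_filament", True, _ST, ()),
    ("FlgD", "hook_filament", True, _ST, ()),
    ("FliK", "hook_filament", False, _ST, ()),
    ("FlgK", "hook_filament", True, _ST, ()),
    ("FlgL", "hook_filament", True, _ST, ()),
    ("FlgN", "hook_filament", False, _ST, ()),
    ("FliC", "hook_filament", True, _ST, ()),
    ("FliD", "hook_filament", True, _ST, ()),
    ("FliS", "hook_filament", False, _ST, ()),
    ("FliT", "hook_filament", False, _ST, ()),
    ("YvyC", "hook_filament", False, _BS, ("FlaG",)),
    # regulators and others (10)
    ("FlhC", "regulator", False, _ST, ()),
    ("FlhD", "regulator", False, _ST, ()),
    ("SwrA", "regulator", False, _BS, ()),
    ("SwrB", "regulator", False, _BS, ()),
    ("FliA", "regulator", False, _BS, ()),
    ("FlgM", "regulator", False, _ST, ()),
    ("CsrA", "regulator", False, _BS, ()),
    ("FliW", "regulator", False, _BS, ()),
    ("FlhF", "regulator", False, _BS, ()),
    ("FlhG", "regulator", False, _BS, ()),
]

# F5 operon order: kinase with extra CheW domain, then CheW, arbitrary
# interleaved receptors / response regulators, then CheB-CheR.
_F_CLASS_TABLE: list[tuple[str, frozenset, frozenset, str, bool, str]] = [
    (
        "F1",
        frozenset({"CheA", "CheW", "CheB", "CheR", "CheC", "CheD"}),
        frozenset({"CheC", "CheD"}),
        "",  # no conserved gene order reported for F1
        False,
        "44H",
    ),
    (
        "F5",
        frozenset({"CheA", "CheW", "CheB", "CheR"}),
        frozenset(),
        "A:W W ... B R",
        True,
        "38H",
    ),
    # F7/F9/ACF signatures are editable placeholders (component sets only);
    # the published discrimination scheme is profile-based and richer.
    (
        "F7",
        frozenset({"CheA", "CheW", "CheB", "CheR", "CheY"}),
        frozenset(),
        "",
        False,
        "36H",
    ),
    (
        "F9",
        frozenset({"CheA", "CheW", "CheB", "CheR", "CheX", "CheY"}),
        frozenset(),
        "",
        False,
        "44H",
    ),
    (
        "ACF",
        frozenset({"CheA", "CheW", "CheB", "CheR"}),
        frozenset(),
        "",
        False,
        "40H",
    ),
]

#: Classification precedence: most specific signature first.
F_CLASS_PRECEDENCE = ("F1", "F5", "F9", "F7", "ACF")

_H_CLASS_TABLE = [24, 28, 34, 36, 38, 40, 44, 48, 52, 58, 64]


@dataclass
class Registry:
    """Immutable-by-convention container of all reference definitions."""

    genes: dict[str, GeneDef] = field(default_factory=dict)
    f_classes: dict[str, FClassDef] = field(default_factory=dict)
    h_classes: dict[str, HClassDef] = field(default_factory=dict)

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        names = list(self.genes)
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise RegistryValidationError(f"duplicate gene name(s): {dupes}")
        all_aliases: dict[str, str] = {}
        for g in self.genes.values():
            if g.category not in CATEGORIES:
                raise RegistryValidationError(
                    f"{g.name}: unknown category {g.category!r}"
                )
            for a in g.aliases:
                if a in self.genes:
                    raise RegistryValidationError(
                        f"alias {a!r} of {g.name} collides with a gene name"
                    )
                if a in all_aliases:
                    raise RegistryValidationError(
                        f"alias {a!r} shared by {all_aliases[a]} and {g.name}"
                    )
                all_aliases[a] = g.name
        n_core = sum(g.is_core for g in self.genes.values())
        if n_core != 24:
            raise RegistryValidationError(
                f"core subset must have exactly 24 genes, found {n_core}"
            )
        for fc in self.f_classes.values():
            if fc.kinase_variant and fc.name != "F5":
                raise RegistryValidationError(
                    f"only F5 may set kinase_variant (got {fc.name})"
                )
            if not fc.required_components:
                raise RegistryValidationError(f"{fc.name}: empty required set")
            if fc.cognate_h and fc.cognate_h not in self.h_classes:
                raise RegistryValidationError(
                    f"{fc.name}: unknown cognate H class {fc.cognate_h!r}"
                )
        if "F5" in self.f_classes and not self.f_classes["F5"].order_pattern:
            raise RegistryValidationError("F5 requires an order_pattern")
        for h in self.h_classes.values():
            if h.heptad_count <= 0:
                raise RegistryValidationError(f"{h.label}: heptad_count <= 0")

    # -- accessors ----------------------------------------------------------

    @property
    def gene_order(self) -> list[str]:
        """Gene symbols in catalog (presence-matrix column) order."""
        return list(self.genes)

    def core_gene_set(self) -> set[str]:
        """The 24-member ancient structural core."""
        return {g.name for g in self.genes.values() if g.is_core}

    def resolve_symbol(self, symbol: str) -> str | None:
        """Map a gene symbol or alias to its canonical catalog name."""
        if symbol in self.genes:
            return symbol
        for g in self.genes.values():
            if symbol in g.aliases:
                return g.name
        return None

    def category_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {c: 0 for c in CATEGORIES}
        for g in self.genes.values():
            sizes[g.category] += 1
        return sizes


def _builtin_registry() -> Registry:
    reg = Registry(
        genes={
            name: GeneDef(name, cat, core, src, aliases)
            for name, cat, core, src, aliases in _GENE_TABLE
        },
        f_classes={
            name: FClassDef(name, req, diag, pattern, kv, ch)
            for name, req, diag, pattern, kv, ch in _F_CLASS_TABLE
        },
        h_classes={f"{n}H": HClassDef(f"{n}H", n) for n in _H_CLASS_TABLE},
    )
    reg.validate()
    return reg


# ---------------------------------------------------------------------------
# Plain-text serialization
#
# Sectioned TSV: a "[section]" line opens each block, the next line is the
# header, following lines are tab-separated rows.  Empty set / pattern
# fields are written as "-".  Lines starting with "#" are comments.
# ---------------------------------------------------------------------------


def _join(items) -> str:
    return ",".join(sorted(items)) if items else "-"


def _split(cell: str) -> frozenset[str]:
    return frozenset() if cell == "-" else frozenset(cell.split(","))


def write_registry(registry: Registry, path: str) -> None:
    """Serialize a registry to its sectioned-TSV text form."""
    lines = ["# flagscan registry", "[genes]",
             "name\tcategory\tcore\tquery_source\taliases"]
    for g in registry.genes.values():
        lines.append(
            f"{g.name}\t{g.category}\t{int(g.is_core)}\t{g.query_source}\t"
            + (",".join(g.aliases) if g.aliases else "-")
        )
    lines += ["[f_classes]",
              "name\trequired\tdiagnostic\torder_pattern\tkinase_variant\tcognate_h"]
    for fc in registry.f_classes.values():
        lines.append(
            f"{fc.name}\t{_join(fc.required_components)}\t"
            f"{_join(fc.diagnostic_components)}\t{fc.order_pattern or '-'}\t"
            f"{int(fc.kinase_variant)}\t{fc.cognate_h or '-'}"
        )
    lines += ["[h_classes]", "label\theptad_count\ttolerance"]
    for h in registry.h_classes.values():
        lines.append(f"{h.label}\t{h.heptad_count}\t{h.tolerance}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _parse_registry_text(text: str) -> Registry:
    reg = Registry()
    section = None
    header: list[str] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        if line.startswith("[") and line.endswith("]"):
            section = line[1:-1]
            header = []
            continue
        if section is None:
            raise RegistryValidationError(
                f"line {lineno}: data before any [section] header"
            )
        cells = line.split("\t")
        if not header:
            header = cells
            continue
        row = dict(zip(header, cells, strict=True))
        if section == "genes":
            g = GeneDef(
                name=row["name"],
                category=row["category"],
                is_core=bool(int(row["core"])),
                query_source=row["query_source"],
                aliases=tuple(row["aliases"].split(","))
                if row["aliases"] != "-"
                else (),
            )
            if g.name in reg.genes:
                raise RegistryValidationError(f"duplicate gene name: {g.name}")
            reg.genes[g.name] = g
        elif section == "f_classes":
            reg.f_classes[row["name"]] = FClassDef(
                name=row["name"],
                required_components=_split(row["required"]),
                diagnostic_components=_split(row["diagnostic"]),
                order_pattern="" if row["order_pattern"] == "-" else row["order_pattern"],
                kinase_variant=bool(int(row["kinase_variant"])),
                cognate_h="" if row["cognate_h"] == "-" else row["cognate_h"],
            )
        elif section == "h_classes":
            reg.h_classes[row["label"]] = HClassDef(
                label=row["label"],
                heptad_count=int(row["heptad_count"]),
                tolerance=int(row["tolerance"]),
            )
        else:
            raise RegistryValidationError(f"unknown section [{section}]")
    reg.validate()
    return reg


def load_registry(config_path: str | None = None) -> Registry:
    """Load the registry from ``config_path``, or the built-in default.

    The built-in default reproduces the reference query catalog: 50
    flagellar genes in six categories (24 of them core), the five
    chemosensory F-class signatures, and the heptad-length classes.
    """
    if config_path is None or config_path == "":
        return _builtin_registry()
    with open(config_path) as fh:
        return _parse_registry_text(fh.read())


def core_gene_set(registry: Registry | None = None) -> set[str]:
    """Return the 24 core flagellar gene symbols."""
    return (registry or _builtin_registry()).core_gene_set()
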