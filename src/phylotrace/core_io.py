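"""Typed data model and TSV readers/writers.

Conventions: coordinates are 1-based and fully closed with VCF-style ref/alt
on the plus strand.  Trinucleotide contexts are stored on the plus strand and
collapsed into the 96 reverse-complement-identical substitution classes by
taking the lexicographically smaller of ``context>alt`` and its reverse
complement.  All tables are UTF-8 TSV with a mandatory header and ``.`` for
missing values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "ValidationError",
    "TrackedVariant",
    "VariantCounts",
    "BackgroundCounts",
    "SampleManifest",
    "CloneTree",
    "collapse_context",
    "revcomp",
    "read_variant_table",
    "read_counts_table",
    "read_background_table",
    "read_manifest",
    "read_clone_tree",
    "write_results",
    "variants_to_frame",
    "counts_to_frame",
]

MISSING = "."

_COMP = str.maketrans("ACGTacgt", "TGCAtgca")


class ValidationError(ValueError):
    """Raised when an input table violates the documented contract."""


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def collapse_context(tnc: str, alt: str) -> str:
    """Collapse a plus-strand context/alternate pair onto its 96-class key."""
    fwd = f"{tnc}>{alt}"
    rev = f"{revcomp(tnc)}>{revcomp(alt)}"
    return min(fwd, rev)


# ---------------------------------------------------------------------------
# record types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrackedVariant:
    """One tumour-informed mutation with its clone and copy-number annotation.

    ``multiplicity`` (m) is the number of mutated DNA copies per mutated cell;
    ``cn_tumour``/``cn_normal`` (CNt/CNn) are total copy numbers at the locus
    in tumour and normal cells.  ``hard_filtered`` variants are excluded from
    every computation; ``mid_filtered`` variants are excluded from presence
    tests only.
    """

    variant_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    tnc: str
    clone_id: str
    is_clonal: bool
    multiplicity: float
    cn_tumour: float
    cn_normal: float = 2.0
    hard_filtered: bool = False
    mid_filtered: bool = False

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"variant {self.variant_id}: pos must be >=1")
        if self.ref == self.alt:
            raise ValidationError(f"variant {self.variant_id}: ref equals alt")
        if len(self.tnc) != 3 or self.tnc[1] != self.ref:
            raise ValidationError(
                f"variant {self.variant_id}: context/ref mismatch ({self.tnc!r} vs {self.ref!r})"
            )
        if not math.isnan(self.multiplicity):
            if self.multiplicity <= 0:
                raise ValidationError(f"variant {self.variant_id}: multiplicity must be positive")
            if self.multiplicity > self.cn_tumour + 1e-9:
                raise ValidationError(
                    f"variant {self.variant_id}: multiplicity exceeds tumour copy number"
                )

    @property
    def tnc_alt(self) -> str:
        return collapse_context(self.tnc, self.alt)

    @property
    def has_cn_annotation(self) -> bool:
        return not (math.isnan(self.multiplicity) or math.isnan(self.cn_tumour))


@dataclass(frozen=True)
class VariantCounts:
    """Deep (UMI-consensus) alternate observations and depth for one variant."""

    sample_id: str
    variant_id: str
    dao: int
    ddp: int

    def __post_init__(self) -> None:
        if self.dao < 0 or self.ddp < 0:
            raise ValidationError(
                f"counts {self.sample_id}/{self.variant_id}: negative dao/ddp"
            )
        if self.dao > self.ddp:
            raise ValidationError(
                f"counts {self.sample_id}/{self.variant_id}: dao ({self.dao}) > ddp ({self.ddp})"
            )

    @property
    def raw_vaf(self) -> float:
        """dao/ddp; NaN when depth is zero."""
        return self.dao / self.ddp if self.ddp > 0 else float("nan")


@dataclass(frozen=True)
class BackgroundCounts:
    """Aggregated non-variant (background) counts for one 96-class context."""

    sample_id: str
    tnc_alt: str
    dao_total: int
    ddp_total: int

    def __post_init__(self) -> None:
        if self.dao_total > self.ddp_total:
            raise ValidationError(
                f"background {self.sample_id}/{self.tnc_alt}: dao_total > ddp_total"
            )
        ctx, _, alt = self.tnc_alt.partition(">")
        if len(ctx) != 3 or len(alt) != 1:
            raise ValidationError(f"background class key malformed: {self.tnc_alt!r}")
        if collapse_context(ctx, alt) != self.tnc_alt:
            raise ValidationError(
                f"background class {self.tnc_alt!r} is not reverse-complement collapsed"
            )


@dataclass(frozen=True)
class SampleManifest:
    sample_id: str
    patient_id: str
    input_ng: float
    day_from_surgery: int
    phase: str  # preoperative | postoperative

    def __post_init__(self) -> None:
        if not self.input_ng > 0:
            raise ValidationError(f"sample {self.sample_id}: input_ng must be positive")
        if self.phase not in ("preoperative", "postoperative"):
            raise ValidationError(f"sample {self.sample_id}: unknown phase {self.phase!r}")


class CloneTree:
    """Rooted phylogeny of mutation clusters.

    Parameters
    ----------
    parent : mapping clone_id -> parent_id, with ``None`` for the root.
    primary_tumour : per-clone flag; clones found only in surgically excised
        metastases (lymph nodes / intrapulmonary) carry ``False``.
    variants : optional per-clone list of variant ids.
    """

    def __init__(
        self,
        parent: Mapping[str, str | None],
        primary_tumour: Mapping[str, bool] | None = None,
        variants: Mapping[str, Sequence[str]] | None = None,
    ) -> None:
        self.parent = dict(parent)
        roots = [c for c, p in self.parent.items() if p is None]
        if len(roots) != 1:
            raise ValidationError(f"tree must have exactly one root, found {len(roots)}")
        self.root = roots[0]
        for clone, par in self.parent.items():
            if par is not None and par not in self.parent:
                raise ValidationError(f"clone {clone!r} has unknown parent {par!r}")
        self._check_acyclic()
        self.primary_tumour = {
            c: bool(primary_tumour.get(c, True)) if primary_tumour else True
            for c in self.parent
        }
        self.variants = {c: list((variants or {}).get(c, [])) for c in self.parent}
        self.children: dict[str, list[str]] = {c: [] for c in self.parent}
        for clone, par in self.parent.items():
            if par is not None:
                self.children[par].append(clone)
        for kids in self.children.values():
            kids.sort()

    def _check_acyclic(self) -> None:
        for clone in self.parent:
            seen = set()
            node: str | None = clone
            while node is not None:
                if node in seen:
                    raise ValidationError(f"cycle detected through clone {clone!r}")
                seen.add(node)
                node = self.parent[node]

    @property
    def clones(self) -> list[str]:
        return list(self.topological_order())

    def topological_order(self) -> list[str]:
        """Root-first ordering (parents before children)."""
        order: list[str] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            order.append(node)
            stack.extend(reversed(self.children[node]))
        return order

    def ancestors(self, clone: str) -> list[str]:
        """Proper ancestors, nearest first."""
        out = []
        node = self.parent[clone]
        while node is not None:
            out.append(node)
            node = self.parent[node]
        return out

    def descendants(self, clone: str) -> list[str]:
        out: list[str] = []
        stack = list(self.children[clone])
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(self.children[node])
        return out

    def is_ancestor(self, a: str, b: str) -> bool:
        """True if ``a`` is a proper ancestor of ``b``."""
        return a in self.ancestors(b)

    def depth(self, clone: str) -> int:
        return len(self.ancestors(clone))

    def validate_against_variants(self, variants: Iterable[TrackedVariant]) -> None:
        clone_ids = {v.clone_id for v in variants}
        missing = clone_ids - set(self.parent)
        if missing:
            raise ValidationError(f"variants reference clones absent from tree: {sorted(missing)}")

    def __eq__(self, other: object) -> bool:
        return isinstance(other, CloneTree) and self.parent == other.parent

    def __repr__(self) -> str:  # pragma: no cover
        return f"CloneTree(root={self.root!r}, n_clones={len(self.parent)})"


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

_VARIANT_COLS = [
    "variant_id", "chrom", "pos", "ref", "alt", "tnc", "clone_id", "is_clonal",
    "multiplicity", "cn_tumour", "cn_normal", "hard_filtered", "mid_filtered",
]
_COUNT_COLS = ["sample_id", "variant_id", "dao", "ddp"]
_BACKGROUND_COLS = ["sample_id", "tnc_alt", "dao_total", "ddp_total"]
_MANIFEST_COLS = ["sample_id", "patient_id", "input_ng", "day_from_surgery", "phase"]


def _read_tsv(path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")
    return df


def _parse(row_ix: int, field_name: str, raw: str, caster, path):
    if raw == MISSING or raw == "":
        return float("nan") if caster is float else None
    try:
        return caster(raw)
    except (TypeError, ValueError):
        raise ValidationError(
            f"{path} row {row_ix}: field {field_name!r} malformed value {raw!r}"
        ) from None


def _parse_bool(row_ix: int, field_name: str, raw: str, path) -> bool:
    low = raw.strip().lower()
    if low in ("true", "1", "yes"):
        return True
    if low in ("false", "0", "no", MISSING, ""):
        return False
    raise ValidationError(f"{path} row {row_ix}: field {field_name!r} malformed value {raw!r}")


def read_variant_table(path) -> list[TrackedVariant]:
    df = _read_tsv(path, _VARIANT_COLS)
    out = []
    for ix, row in enumerate(df.itertuples(index=False), 1):
        pos = _parse(ix, "pos", row.pos, int, path)
        if pos is None or pos < 1:
            raise ValidationError(f"{path} row {ix}: pos must be >=1")
        cn_normal = _parse(ix, "cn_normal", row.cn_normal, float, path)
        try:
            out.append(
                TrackedVariant(
                    variant_id=row.variant_id,
                    chrom=row.chrom,
                    pos=pos,
                    ref=row.ref,
                    alt=row.alt,
                    tnc=row.tnc,
                    clone_id=row.clone_id,
                    is_clonal=_parse_bool(ix, "is_clonal", row.is_clonal, path),
                    multiplicity=_parse(ix, "multiplicity", row.multiplicity, float, path),
                    cn_tumour=_parse(ix, "cn_tumour", row.cn_tumour, float, path),
                    cn_normal=2.0 if math.isnan(cn_normal) else cn_normal,
                    hard_filtered=_parse_bool(ix, "hard_filtered", row.hard_filtered, path),
                    mid_filtered=_parse_bool(ix, "mid_filtered", row.mid_filtered, path),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path} row {ix}: {exc}") from None
    return out


def read_counts_table(path) -> list[VariantCounts]:
    df = _read_tsv(path, _COUNT_COLS)
    out = []
    for ix, row in enumerate(df.itertuples(index=False), 1):
        try:
            out.append(
                VariantCounts(
                    sample_id=row.sample_id,
                    variant_id=row.variant_id,
                    dao=_parse(ix, "dao", row.dao, int, path),
                    ddp=_parse(ix, "ddp", row.ddp, int, path),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path} row {ix}: {exc}") from None
    return out


def read_background_table(path) -> list[BackgroundCounts]:
    df = _read_tsv(path, _BACKGROUND_COLS)
    out = []
    for ix, row in enumerate(df.itertuples(index=False), 1):
        try:
            out.append(
                BackgroundCounts(
                    sample_id=row.sample_id,
                    tnc_alt=row.tnc_alt,
                    dao_total=_parse(ix, "dao_total", row.dao_total, int, path),
                    ddp_total=_parse(ix, "ddp_total", row.ddp_total, int, path),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path} row {ix}: {exc}") from None
    return out


def read_manifest(path) -> list[SampleManifest]:
    df = _read_tsv(path, _MANIFEST_COLS)
    out = []
    for ix, row in enumerate(df.itertuples(index=False), 1):
        try:
            out.append(
                SampleManifest(
                    sample_id=row.sample_id,
                    patient_id=row.patient_id,
                    input_ng=_parse(ix, "input_ng", row.input_ng, float, path),
                    day_from_surgery=_parse(ix, "day_from_surgery", row.day_from_surgery, int, path),
                    phase=row.phase,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path} row {ix}: {exc}") from None
    return out


def _tree_from_newick(text: str) -> CloneTree:
    """Parse a single labelled Newick tree, e.g. ``((b)a)root;``."""
    s = text.strip().rstrip(";")
    parent: dict[str, str | None] = {}
    pos = 0

    def node(par_slot: list[tuple[str, str | None]]) -> str:
        nonlocal pos
        kids: list[str] = []
        if pos < len(s) and s[pos] == "(":
            pos += 1
            while True:
                kids.append(node(par_slot))
                if pos >= len(s):
                    raise ValidationError("unbalanced parentheses in Newick tree")
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
                raise ValidationError(f"unexpected character {s[pos]!r} in Newick tree")
        start = pos
        while pos < len(s) and s[pos] not in "(),":
            pos += 1
        label = s[start:pos].split(":", 1)[0].strip()
        if not label:
            raise ValidationError("Newick tree contains an unlabelled node")
        if label in parent:
            raise ValidationError(f"duplicate clone label {label!r} in Newick tree")
        parent[label] = None
        for kid in kids:
            parent[kid] = label
        return label

    root = node([])
    if pos != len(s):
        raise ValidationError("trailing characters after Newick tree")
    parent[root] = None
    return CloneTree(parent)


def read_clone_tree(path) -> CloneTree:
    """Read a clone tree from a parent-child TSV or a Newick file.

    TSV columns: ``clone_id, parent_id, primary_tumour`` (``.`` parent marks
    the root).  Files ending in ``.nwk``/``.newick``/``.tree`` are parsed as
    single-tree Newick with clone labels on every node.
    """
    spath = str(path)
    if spath.endswith((".nwk", ".newick", ".tree")):
        with open(path) as fh:
            return _tree_from_newick(fh.read())
    df = _read_tsv(path, ["clone_id", "parent_id"])
    parent: dict[str, str | None] = {}
    primary: dict[str, bool] = {}
    for ix, row in enumerate(df.itertuples(index=False), 1):
        clone = row.clone_id
        if clone in parent:
            raise ValidationError(f"{path} row {ix}: duplicate clone_id {clone!r}")
        par = None if row.parent_id in (MISSING, "", "NA") else row.parent_id
        parent[clone] = par
        if "primary_tumour" in df.columns:
            primary[clone] = _parse_bool(ix, "primary_tumour", row.primary_tumour, path)
    # a parent referenced but not listed as a row is treated as the root label
    referenced = {p for p in parent.values() if p is not None}
    for p in referenced - set(parent):
        parent[p] = None
        primary.setdefault(p, True)
    return CloneTree(parent, primary if primary else None)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_results(results, path, format: str = "tsv") -> None:
    """Write a result table deterministically.

    ``results`` may be a DataFrame or an iterable of dataclass records; column
    order follows the input, floats are emitted via repr round-trip so the
    matching reader reproduces identical values.
    """
    if format != "tsv":
        raise ValueError(f"unsupported format {format!r}")
    if isinstance(results, pd.DataFrame):
        df = results.copy()
    else:
        rows = [r.__dict__ if hasattr(r, "__dict__") else dict(r) for r in results]
        df = pd.DataFrame(rows)
    # shortest-repr floats so the matching reader reproduces identical values
    df.to_csv(path, sep="\t", index=False, na_rep=MISSING,
              float_format=lambda x: repr(float(x)))


def variants_to_frame(variants: Iterable[TrackedVariant]) -> pd.DataFrame:
    return pd.DataFrame([v.__dict__ for v in variants], columns=_VARIANT_COLS)


def counts_to_frame(counts: Iterable[VariantCounts]) -> pd.DataFrame:
    df = pd.DataFrame([c.__dict__ for c in counts], columns=_COUNT_COLS)
    return df
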