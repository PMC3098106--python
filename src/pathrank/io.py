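"""Containers and file I/O for expression matrices, class labels and gene sets.

The on-disk formats are deliberately plain:

* expression matrix — tab-separated text, one row per gene, first column the
  gene identifier, header row of sample identifiers;
* class labels — two tab-separated columns ``sample_id<TAB>group`` (a Broad
  CLS file is also accepted and detected automatically);
* gene sets — GMT (Broad dialect): ``name<TAB>description<TAB>gene1<TAB>...``.

Gene identifiers are matched by exact, case-sensitive string equality
throughout; no probe-to-symbol mapping is attempted.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("pathrank")

__all__ = [
    "ExpressionMatrix",
    "GeneSet",
    "GeneSetCollection",
    "ParseError",
    "ConsistencyError",
    "ValidationError",
    "PathwayTooSmallError",
    "read_expression",
    "write_expression",
    "read_classes",
    "read_cls",
    "read_gmt",
    "write_gmt",
    "subset_to_pathway",
]


class ParseError(ValueError):
    """A file could not be parsed under its declared format."""


class ConsistencyError(ValueError):
    """Two inputs that must agree (matrix vs class labels) do not."""


class ValidationError(ValueError):
    """An in-memory object violates one of its invariants."""


class PathwayTooSmallError(Exception):
    """A gene set overlaps the array in fewer than ``min_genes`` genes.

    Callers iterating over a collection should catch this and skip the set.
    """

    def __init__(self, name: str, n_overlap: int, min_genes: int):
        self.name = name
        self.n_overlap = n_overlap
        self.min_genes = min_genes
        super().__init__(
            f"gene set {name!r}: only {n_overlap} gene(s) present on the array "
            f"(minimum {min_genes})"
        )


@dataclass
class ExpressionMatrix:
    """A genes x samples matrix of log-scale intensities with two-group labels.

    Parameters
    ----------
    values
        Real matrix of shape ``(n_genes, n_samples)``; no missing values.
    gene_ids, sample_ids
        Unique, ordered identifiers for the rows and columns.
    groups
        Per-sample class label; exactly two distinct labels, each with at
        least two samples.
    classes
        Ordered pair of the two labels.  ``classes[0]`` is the condition of
        interest (the "treated"/test class): signal-to-noise ratios are
        computed as mean(classes[0]) − mean(classes[1]).  Defaults to order
        of first appearance in ``groups``.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    groups: list[str]
    classes: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.groups = [str(g) for g in self.groups]
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D genes x samples matrix")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} gene_ids x {len(self.sample_ids)} sample_ids"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("gene_ids are not unique")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("sample_ids are not unique")
        if len(self.groups) != len(self.sample_ids):
            raise ValidationError("one group label per sample is required")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("values contain missing or non-finite entries")
        distinct = list(dict.fromkeys(self.groups))
        if len(distinct) != 2:
            raise ValidationError(
                f"exactly two group labels required, found {len(distinct)}: {distinct}"
            )
        if self.classes is None:
            self.classes = (distinct[0], distinct[1])
        else:
            self.classes = (str(self.classes[0]), str(self.classes[1]))
            if set(self.classes) != set(distinct):
                raise ValidationError(
                    f"classes {self.classes} do not match group labels {distinct}"
                )
        for label in self.classes:
            if self.groups.count(label) < 2:
                raise ValidationError(f"group {label!r} has fewer than 2 samples")

    # -- basic geometry ----------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def group_sizes(self) -> tuple[int, int]:
        """(n1, n2) for (classes[0], classes[1])."""
        n1 = self.groups.count(self.classes[0])
        return n1, self.n_samples - n1

    def group_mask(self) -> np.ndarray:
        """Boolean membership of each sample in ``classes[0]``."""
        return np.array([g == self.classes[0] for g in self.groups], dtype=bool)

    # -- derived views -----------------------------------------------------
    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        """Restrict to ``genes`` (which must all be present), preserving row order."""
        wanted = set(genes)
        idx = [i for i, g in enumerate(self.gene_ids) if g in wanted]
        return replace(
            self,
            values=self.values[idx, :],
            gene_ids=[self.gene_ids[i] for i in idx],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        groups: Sequence[str],
        classes: tuple[str, str] | None = None,
    ) -> "ExpressionMatrix":
        return cls(
            values=frame.to_numpy(dtype=float),
            gene_ids=[str(i) for i in frame.index],
            sample_ids=[str(c) for c in frame.columns],
            groups=list(groups),
            classes=classes,
        )


@dataclass(frozen=True)
class GeneSet:
    """A named, duplicate-free collection of gene identifiers."""

    name: str
    genes: frozenset[str]
    description: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", frozenset(str(g) for g in self.genes))
        if not self.genes:
            raise ValidationError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes


@dataclass
class GeneSetCollection:
    """An ordered collection of uniquely named gene sets (file order preserved)."""

    sets: list[GeneSet] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValidationError(f"duplicate gene-set names: {dupes}")

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, key: int | str) -> GeneSet:
        if isinstance(key, str):
            for s in self.sets:
                if s.name == key:
                    return s
            raise KeyError(key)
        return self.sets[key]

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sets]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_classes(path: str | Path) -> tuple[dict[str, str], tuple[str, ...]]:
    """Read sample class labels from a two-column TSV or a Broad CLS file.

    Returns a mapping ``sample_id -> group`` (empty sample ids only for CLS,
    where positional labels ``s1, s2, ...`` are synthesised) and the class
    labels in order of first appearance.
    """
    path = Path(path)
    lines = [ln.rstrip("\n") for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: empty class file")
    first = lines[0].split()
    if len(first) == 3 and all(tok.lstrip("-").isdigit() for tok in first):
        return _parse_cls(lines, path)
    mapping: dict[str, str] = {}
    order: list[str] = []
    for i, ln in enumerate(lines, start=1):
        fields = ln.split("\t")
        if len(fields) != 2:
            raise ParseError(
                f"{path}:{i}: expected two tab-separated fields, got {len(fields)}"
            )
        sample, group = fields[0].strip(), fields[1].strip()
        if sample in mapping:
            raise ParseError(f"{path}:{i}: duplicate sample id {sample!r}")
        mapping[sample] = group
        if group not in order:
            order.append(group)
    return mapping, tuple(order)


def _parse_cls(lines: list[str], path: Path) -> tuple[dict[str, str], tuple[str, ...]]:
    if len(lines) < 3:
        raise ParseError(f"{path}: CLS file needs 3 lines")
    n_samples = int(lines[0].split()[0])
    names = lines[1].lstrip("#").split()
    labels = lines[2].split()
    if len(labels) != n_samples:
        raise ParseError(
            f"{path}: CLS header declares {n_samples} samples, line 3 has {len(labels)}"
        )
    # numeric CLS labels index into the name list in order of first use
    if all(l.lstrip("-").isdigit() for l in labels) and names:
        seen: dict[str, str] = {}
        resolved = []
        for l in labels:
            if l not in seen:
                seen[l] = names[len(seen)] if len(seen) < len(names) else l
            resolved.append(seen[l])
        labels = resolved
    mapping = {f"s{i + 1}": lab for i, lab in enumerate(labels)}
    order = tuple(dict.fromkeys(labels))
    return mapping, order


def read_cls(path: str | Path) -> tuple[dict[str, str], tuple[str, ...]]:
    """Convenience alias for reading a Broad CLS class file."""
    return read_classes(path)


def read_expression(path: str | Path, class_path: str | Path) -> ExpressionMatrix:
    """Read a TSV expression matrix together with a sample class file.

    Rows containing any missing (or non-numeric) value are dropped with a
    warning.  Duplicate gene identifiers keep the first row's name; later
    rows are suffixed ``.dupN`` and a warning is logged.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0, header=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas message varies
        raise ParseError(f"{path}: cannot parse as TSV ({exc})") from exc
    if frame.shape[1] == 0:
        raise ParseError(f"{path}: header row defines no sample columns")
    if any(str(c).startswith("Unnamed:") or str(c).strip() == "" for c in frame.columns):
        raise ParseError(f"{path}: malformed header (blank or unnamed sample columns)")

    # de-duplicate gene ids, keeping first occurrence's name
    counts: dict[str, int] = {}
    new_index = []
    for g in frame.index.astype(str):
        if g in counts:
            counts[g] += 1
            suffixed = f"{g}.dup{counts[g]}"
            logger.warning("duplicate gene id %r renamed to %r", g, suffixed)
            new_index.append(suffixed)
        else:
            counts[g] = 0
            new_index.append(g)
    frame.index = new_index

    numeric = frame.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1)
    if bad.any():
        dropped = list(numeric.index[bad])
        logger.warning(
            "dropping %d gene row(s) with missing values: %s",
            len(dropped),
            ", ".join(dropped[:10]) + ("..." if len(dropped) > 10 else ""),
        )
        numeric = numeric.loc[~bad]

    mapping, order = read_classes(class_path)
    sample_ids = [str(c) for c in numeric.columns]
    extra = [s for s in mapping if s not in sample_ids]
    if extra:
        raise ConsistencyError(
            f"class file lists sample(s) absent from the matrix: {extra}"
        )
    missing = [s for s in sample_ids if s not in mapping]
    if missing:
        raise ConsistencyError(
            f"matrix sample(s) missing from the class file: {missing}"
        )
    groups = [mapping[s] for s in sample_ids]
    if len(order) != 2:
        raise ValidationError(
            f"exactly two group labels required, class file has {len(order)}: {list(order)}"
        )
    return ExpressionMatrix.from_frame(numeric, groups, classes=(order[0], order[1]))


def write_expression(
    X: ExpressionMatrix, path: str | Path, class_path: str | Path | None = None
) -> None:
    """Write a matrix (and optionally its class labels) back to TSV."""
    X.to_frame().to_csv(path, sep="\t", index_label="gene_id")
    if class_path is not None:
        with open(class_path, "w") as fh:
            for s, g in zip(X.sample_ids, X.groups):
                fh.write(f"{s}\t{g}\n")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT gene-set file (name, description, then genes; tab-separated)."""
    path = Path(path)
    sets: list[GeneSet] = []
    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{i}: GMT line needs >= 3 tab-separated fields, got {len(fields)}"
                )
            name, desc, genes = fields[0], fields[1], [g for g in fields[2:] if g.strip()]
            unique = list(dict.fromkeys(genes))
            if len(unique) != len(genes):
                logger.warning(
                    "%s:%d: gene set %r contains duplicate genes; deduplicated",
                    path,
                    i,
                    name,
                )
            if not unique:
                raise ParseError(f"{path}:{i}: gene set {name!r} lists no genes")
            sets.append(GeneSet(name=name, description=desc, genes=frozenset(unique)))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.description, *sorted(s.genes)]) + "\n")


def subset_to_pathway(
    X: ExpressionMatrix, g: GeneSet, min_genes: int = 2
) -> ExpressionMatrix:
    """Restrict ``X`` to the genes of ``g``, preserving ``X``'s gene order.

    Raises :class:`PathwayTooSmallError` when fewer than ``min_genes`` genes
    of the set are present on the array; callers iterating a collection
    should catch it and skip the set.
    """
    if min_genes < 1:
        raise ValueError("min_genes must be >= 1")
    overlap = [gene for gene in X.gene_ids if gene in g.genes]
    if len(overlap) < min_genes:
        raise PathwayTooSmallError(g.name, len(overlap), min_genes)
    if len(overlap) == X.n_genes:
        return X
    return X.subset_genes(overlap)
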