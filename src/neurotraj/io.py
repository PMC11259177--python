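"""Reading and writing the plain-text interchange formats.

Count matrices travel as CellRanger-style Matrix Market triplets
(``matrix.mtx[.gz]`` + ``features.tsv`` + ``barcodes.tsv``); gene sets as
GMT; everything tabular as UTF-8 TSV with a header and '.' decimals so the
outputs stay language-neutral.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

#: Float format used for every numeric TSV the package writes. Fixing it
#: makes byte-level reproducibility of a rerun checkable.
TSV_FLOAT_FORMAT = "%.6g"


@dataclass
class CountMatrix:
    """Sparse gene-by-nucleus raw integer counts with aligned identifiers."""

    matrix: sp.csc_matrix  # genes x nuclei
    genes: list[str]
    barcodes: list[str]

    def __post_init__(self) -> None:
        self.matrix = sp.csc_matrix(self.matrix)
        if self.matrix.shape != (len(self.genes), len(self.barcodes)):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.genes)} genes x {len(self.barcodes)} barcodes"
            )
        if self.matrix.nnz and self.matrix.data.min() < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_nuclei(self) -> int:
        return self.matrix.shape[1]

    def subset(self, genes: Sequence[str] | None = None,
               barcodes: Sequence[str] | None = None) -> "CountMatrix":
        """Return a new matrix restricted to the given identifiers (order kept)."""
        gidx = np.arange(self.n_genes)
        bidx = np.arange(self.n_nuclei)
        if genes is not None:
            pos = {g: i for i, g in enumerate(self.genes)}
            gidx = np.array([pos[g] for g in genes], dtype=int)
        if barcodes is not None:
            pos = {b: i for i, b in enumerate(self.barcodes)}
            bidx = np.array([pos[b] for b in barcodes], dtype=int)
        return CountMatrix(
            self.matrix[np.ix_(gidx, bidx)],
            [self.genes[i] for i in gidx],
            [self.barcodes[i] for i in bidx],
        )


@dataclass
class RegulonSet:
    """TF -> ordered target gene lists, with an 'extended' flag per regulon."""

    regulons: dict[str, list[str]] = field(default_factory=dict)
    extended: dict[str, bool] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.regulons)

    def sizes(self) -> dict[str, int]:
        return {tf: len(t) for tf, t in self.regulons.items()}


def _dedupe(names: list[str], what: str) -> list[str]:
    """Disambiguate duplicated ids by suffixing '.1', '.2', ...; logged."""
    seen: dict[str, int] = {}
    out = []
    for n in names:
        if n in seen:
            seen[n] += 1
            new = f"{n}.{seen[n]}"
            logger.warning("duplicate %s id %r renamed to %r", what, n, new)
            out.append(new)
        else:
            seen[n] = 0
            out.append(n)
    return out


def _read_tsv_column(path: Path) -> list[str]:
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def _find(dirpath: Path, stem: str) -> Path:
    for cand in (dirpath / stem, dirpath / f"{stem}.gz"):
        if cand.exists():
            return cand
    raise FileNotFoundError(f"missing {stem}[.gz] in {dirpath}")


def read_count_matrix(path: str | Path) -> CountMatrix:
    """Read a CellRanger-style triplet directory into a :class:`CountMatrix`.

    Expects ``matrix.mtx(.gz)``, ``features.tsv(.gz)`` (gene ids in the first
    column) and ``barcodes.tsv(.gz)``. Genes are rows, nuclei columns.
    """
    dirpath = Path(path)
    mtx_path = _find(dirpath, "matrix.mtx")
    if mtx_path.stat().st_size == 0:
        raise ValueError(f"empty matrix file: {mtx_path}")
    mat = sp.csc_matrix(scipy.io.mmread(str(mtx_path)))
    genes = _dedupe(_read_tsv_column(_find(dirpath, "features.tsv")), "gene")
    barcodes = _dedupe(_read_tsv_column(_find(dirpath, "barcodes.tsv")), "barcode")
    if mat.shape != (len(genes), len(barcodes)):
        raise ValueError(
            f"dimension mismatch: matrix is {mat.shape} but features/barcodes "
            f"give {len(genes)} x {len(barcodes)}"
        )
    mat.data = np.rint(mat.data)
    return CountMatrix(mat.astype(np.int64), genes, barcodes)


def write_count_matrix(cm: CountMatrix, path: str | Path) -> None:
    """Write the triplet form (plain text, uncompressed)."""
    dirpath = Path(path)
    dirpath.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(dirpath / "matrix.mtx"), sp.coo_matrix(cm.matrix), field="integer")
    (dirpath / "features.tsv").write_text("".join(f"{g}\n" for g in cm.genes))
    (dirpath / "barcodes.tsv").write_text("".join(f"{b}\n" for b in cm.barcodes))


def read_gene_sets(path: str | Path) -> RegulonSet:
    """Parse a GMT file: name <tab> description <tab> gene1 <tab> gene2 ...

    Order-preserving; duplicated genes within a set are dropped (logged).
    A regulon whose name ends in ``_extended`` gets the extended flag.
    """
    rs = RegulonSet()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has <3 fields")
            name = fields[0]
            genes, seen = [], set()
            for g in fields[2:]:
                if not g:
                    continue
                if g in seen:
                    logger.warning("%s:%d: duplicate gene %r dropped", path, lineno, g)
                    continue
                seen.add(g)
                genes.append(g)
            rs.regulons[name] = genes
            rs.extended[name] = name.endswith("_extended")
    return rs


def write_gene_sets(rs: RegulonSet, path: str | Path,
                    descriptions: Mapping[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for name, genes in rs.regulons.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Write a TSV in the package's canonical form (stable float format)."""
    df.to_csv(path, sep="\t", index=index, float_format=TSV_FLOAT_FORMAT,
              lineterminator="\n")


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
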