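"""Core containers and preprocessing for ASV feature tables.

The pipeline starts where amplicon denoising ends: a samples × taxa count
table, a rooted phylogeny over the taxa, and per-sample metadata.  This
module holds the :class:`CountTable` wrapper, readers/writers for the
standard plain-text formats (TSV, BIOM-HDF5, newick), the low-prevalence
ASV filter (singletons and taxa seen in a single sample are discarded),
and rarefaction to uniform depth.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from skbio import TreeNode

logger = logging.getLogger(__name__)

#: physicochemical factor columns expected in a sample frame (units in docs)
FACTOR_COLUMNS = (
    "moisture",
    "temperature",
    "reducing_sugar",
    "acidity",
    "pH",
    "ethanol",
)


class FormatError(ValueError):
    """Raised when an input file violates the format contract."""


@dataclass(frozen=True)
class CountTable:
    """Samples × taxa matrix of non-negative integer counts.

    Wraps a :class:`pandas.DataFrame` whose index holds sample identifiers
    and whose columns hold taxon (ASV) identifiers.  Identifiers must be
    unique; counts must be non-negative integers.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dupes}")
        if df.columns.has_duplicates:
            dupes = df.columns[df.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate taxon ids: {dupes}")
        if not np.issubdtype(df.to_numpy().dtype, np.integer):
            raise FormatError("counts must be integers")
        if (df.to_numpy() < 0).any():
            r, c = np.argwhere(df.to_numpy() < 0)[0]
            raise FormatError(
                f"negative count at sample {df.index[r]!r}, taxon {df.columns[c]!r}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def sample_totals(self) -> pd.Series:
        return self.data.sum(axis=1)

    def relative(self) -> pd.DataFrame:
        """Relative-abundance view (each row divided by its total).

        Rows with zero total are invalid for downstream analyses and
        raise here rather than propagating NaNs.
        """
        totals = self.data.sum(axis=1)
        if (totals == 0).any():
            empty = totals.index[totals == 0].tolist()
            raise ValueError(f"samples with zero total counts: {empty}")
        return self.data.div(totals, axis=0)

    def presence(self) -> pd.DataFrame:
        """Boolean presence/absence view (count > 0)."""
        return self.data > 0

    def select_samples(self, ids: Iterable[str]) -> "CountTable":
        return CountTable(self.data.loc[list(ids)])


def read_count_table(
    path: str | Path, format: str = "tsv", taxa_as: str = "columns"
) -> CountTable:
    """Read a feature table from TSV or BIOM-HDF5.

    Parameters
    ----------
    path:
        File to read.
    format:
        ``"tsv"`` (header row + row-name column) or ``"biom"`` (BIOM 2.x
        HDF5, which stores observations × samples CSR/CSC sparse data).
    taxa_as:
        For TSV only: whether taxa are ``"columns"`` (default) or
        ``"rows"`` in the file; the returned table is always samples × taxa.
    """
    path = Path(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        if taxa_as == "rows":
            df = df.T
        elif taxa_as != "columns":
            raise ValueError(f"unknown orientation {taxa_as!r}")
        arr = df.to_numpy()
        if arr.dtype == object or not np.issubdtype(arr.dtype, np.number):
            for j, col in enumerate(df.columns):
                coerced = pd.to_numeric(df[col], errors="coerce")
                bad = coerced.isna() & df[col].notna()
                if bad.any():
                    raise FormatError(
                        f"non-numeric cell at row {df.index[bad.argmax()]!r},"
                        f" column {col!r}"
                    )
            raise FormatError("non-numeric cells in table")
        if np.isnan(arr).any():
            r, c = np.argwhere(np.isnan(arr))[0]
            raise FormatError(
                f"missing cell at row {df.index[r]!r}, column {df.columns[c]!r}"
            )
        if (arr < 0).any():
            r, c = np.argwhere(arr < 0)[0]
            raise FormatError(
                f"negative cell {arr[r, c]!r} at row {df.index[r]!r},"
                f" column {df.columns[c]!r}"
            )
        if not np.allclose(arr, np.round(arr)):
            r, c = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
            raise FormatError(
                f"non-integer cell {arr[r, c]!r} at row {df.index[r]!r},"
                f" column {df.columns[c]!r}"
            )
        return CountTable(df.astype(np.int64))
    if format == "biom":
        return _read_biom_hdf5(path)
    raise ValueError(f"unknown format {format!r}")


def _read_biom_hdf5(path: Path) -> CountTable:
    # BIOM 2.x layout: observation/ids, sample/ids, sample/matrix/{data,
    # indices, indptr} holding samples × observations CSR.
    import h5py
    from scipy.sparse import csr_matrix

    with h5py.File(path, "r") as fh:
        obs_ids = [x.decode() if isinstance(x, bytes) else str(x) for x in fh["observation/ids"][:]]
        samp_ids = [x.decode() if isinstance(x, bytes) else str(x) for x in fh["sample/ids"][:]]
        grp = fh["sample/matrix"]
        mat = csr_matrix(
            (grp["data"][:], grp["indices"][:], grp["indptr"][:]),
            shape=(len(samp_ids), len(obs_ids)),
        )
    dense = np.asarray(mat.todense())
    if not np.allclose(dense, np.round(dense)):
        raise FormatError("BIOM table contains non-integer counts")
    df = pd.DataFrame(np.round(dense).astype(np.int64), index=samp_ids, columns=obs_ids)
    return CountTable(df)


def write_count_table(table: CountTable, path: str | Path, taxa_as: str = "columns") -> None:
    """Write a table as TSV (round-trips with :func:`read_count_table`)."""
    df = table.data if taxa_as == "columns" else table.data.T
    df.to_csv(path, sep="\t")


def read_tree(path_or_str: str | Path, default_branch_length: float | None = None) -> TreeNode:
    """Read a rooted newick phylogeny with unique tips and branch lengths.

    Missing branch lengths are rejected by default: phylogenetic
    dissimilarities scale with them, so silently assuming a value would
    corrupt βMNTD and Faith PD magnitudes.  Pass ``default_branch_length``
    to fill them instead.
    """
    text = None
    p = Path(str(path_or_str))
    try:
        if p.exists():
            text = p.read_text()
    except OSError:
        text = None
    if text is None:
        text = str(path_or_str)
    import io as _io

    tree = TreeNode.read(_io.StringIO(text))
    tips = [t.name for t in tree.tips()]
    if len(tips) != len(set(tips)):
        seen, dupes = set(), set()
        for name in tips:
            (dupes if name in seen else seen).add(name)
        raise FormatError(f"duplicate tip labels: {sorted(dupes)}")
    for node in tree.traverse(include_self=False):
        if node.length is None:
            if default_branch_length is None:
                raise FormatError(
                    f"missing branch length above {node.name or '<internal>'!r}"
                )
            node.length = default_branch_length
        elif node.length < 0:
            raise FormatError(f"negative branch length above {node.name!r}")
    if tree.length is None:
        tree.length = 0.0
    return tree


def read_sample_frame(path: str | Path) -> pd.DataFrame:
    """Read sample metadata keyed on sample_id (first column)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        raise FormatError("duplicate sample ids in metadata")
    for col in FACTOR_COLUMNS:
        if col in df.columns and (pd.to_numeric(df[col], errors="coerce") < 0).any():
            raise FormatError(f"negative values in factor {col!r}")
    return df


_SAMPLE_ID_RE = re.compile(
    r"^(?P<group>[PT])(?P<stage>SAC|FER)(?P<time>\d+)(?P<unit>[hd])(?P<batch>\d+)$"
)


def parse_sample_id(sample_id: str) -> dict:
    """Parse the study's naming convention, e.g. ``TFER3d1``.

    Group letter (P/T), stage (SAC/FER), time point with unit (hours for
    saccharification, days for fermentation), batch number.  Convenience
    only — no pipeline step requires ids in this form.
    """
    m = _SAMPLE_ID_RE.match(sample_id)
    if m is None:
        raise ValueError(f"sample id {sample_id!r} does not follow the naming convention")
    return {
        "group": "PS" if m["group"] == "P" else "TS",
        "stage": m["stage"],
        "time_point": int(m["time"]),
        "time_unit": "hours" if m["unit"] == "h" else "days",
        "batch": int(m["batch"]),
    }


def filter_asvs(table: CountTable) -> CountTable:
    """Drop singleton ASVs and ASVs observed in only one sample.

    A taxon is removed when its total count is 1 (singleton) or when it is
    non-zero in at most one sample; this includes all-zero taxa.  The
    sample set is unchanged.  Idempotent.
    """
    totals = table.data.sum(axis=0)
    n_samples_present = (table.data > 0).sum(axis=0)
    keep = (totals > 1) & (n_samples_present > 1)
    removed = table.data.columns[~keep].tolist()
    if removed:
        logger.info("filter_asvs removed %d taxa: %s", len(removed), removed[:20])
    if keep.sum() == 0:
        logger.warning("filter_asvs removed every taxon; returning an empty table")
    return CountTable(table.data.loc[:, keep])


def rarefy(
    table: CountTable,
    depth: int | None = None,
    seed: int | None = None,
    drop_shallow: bool = False,
) -> CountTable:
    """Subsample each sample without replacement to a uniform depth.

    ``depth`` defaults to the minimum sample total (the usual
    rarefy-to-lowest rule).  Sampling is a multivariate hypergeometric
    draw from each row's multiset of counts — a single draw, not an
    average over repeats.  Deterministic for a given ``seed``.
    """
    if depth is None:
        depth = int(table.sample_totals().min())
    if depth <= 0:
        raise ValueError("depth must be positive")
    totals = table.sample_totals()
    too_shallow = totals.index[totals < depth].tolist()
    if too_shallow and not drop_shallow:
        raise ValueError(
            f"samples shallower than depth {depth}: {too_shallow}; "
            "pass drop_shallow=True to drop them"
        )
    if too_shallow:
        logger.warning("dropping %d samples shallower than %d: %s", len(too_shallow), depth, too_shallow)
    keep = [s for s in table.sample_ids if s not in set(too_shallow)]
    rng = np.random.default_rng(seed)
    out = np.empty((len(keep), table.shape[1]), dtype=np.int64)
    for i, s in enumerate(keep):
        row = table.data.loc[s].to_numpy()
        if row.sum() == depth:
            out[i] = row
        else:
            out[i] = rng.multivariate_hypergeometric(row, depth)
    return CountTable(pd.DataFrame(out, index=keep, columns=table.taxon_ids))
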