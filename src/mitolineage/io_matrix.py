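"""Reading, writing and validation of per-cell mitochondrial VAF matrices.

The canonical on-disk layout is a set of delimited text matrices
(mutations x cells) sharing row and column identifiers: a VAF matrix of
fractions, a depth matrix of total read counts and an alt matrix of
alternate-supporting read counts, plus an optional two-column cell
annotation table.  Matrices are aligned by identifier, never by position,
so files whose rows or columns are permutations of each other load to
equal datasets.

A cell not covered at a site (depth 0) is genuinely missing evidence and
is distinct from an observed VAF of 0 (covered, reference allele); missing
entries are carried as NaN in the VAF matrix.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

MT_GENOME_LENGTH = 16_569  # rCRS human mitochondrial reference

_MUTATION_RE = re.compile(r"^MT_(\d+)_([ACGT])-([ACGT])$")
_BASES = frozenset("ACGT")


@dataclass(frozen=True, order=True)
class MutationId:
    """A mitochondrial SNV, 1-based on the 16,569-bp human MT reference.

    The canonical string form is ``MT_<position>_<ref>-<alt>``, e.g.
    ``MT_16389_G-A``.
    """

    position: int
    ref_base: str
    alt_base: str

    def __post_init__(self) -> None:
        if not 1 <= self.position <= MT_GENOME_LENGTH:
            raise ValueError(
                f"position {self.position} outside 1..{MT_GENOME_LENGTH}"
            )
        if self.ref_base not in _BASES or self.alt_base not in _BASES:
            raise ValueError(f"bases must be one of A/C/G/T: {self}")
        if self.ref_base == self.alt_base:
            raise ValueError(f"ref and alt bases identical: {self}")

    @classmethod
    def parse(cls, s: str) -> "MutationId":
        m = _MUTATION_RE.match(s.strip())
        if m is None:
            raise ValueError(f"unparseable mutation identifier: {s!r}")
        return cls(int(m.group(1)), m.group(2), m.group(3))

    def __str__(self) -> str:
        return f"MT_{self.position}_{self.ref_base}-{self.alt_base}"


@dataclass
class VafDataset:
    """Mutations x cells VAF matrix with companion depth / alt matrices.

    ``vaf`` holds fractions in [0, 1] with NaN where ``depth`` is 0;
    ``alt[x, c] <= depth[x, c]`` everywhere and ``vaf = alt / depth`` on
    covered entries.
    """

    mutations: list[MutationId]
    cells: list[str]
    vaf: np.ndarray
    depth: np.ndarray
    alt: np.ndarray
    cell_annotations: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.vaf = np.asarray(self.vaf, dtype=float)
        self.depth = np.asarray(self.depth, dtype=np.int64)
        self.alt = np.asarray(self.alt, dtype=np.int64)
        self.validate()

    @property
    def n_mutations(self) -> int:
        return len(self.mutations)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def mutation_names(self) -> list[str]:
        return [str(m) for m in self.mutations]

    def validate(self) -> None:
        shape = (self.n_mutations, self.n_cells)
        for name, mat in (("vaf", self.vaf), ("depth", self.depth), ("alt", self.alt)):
            if mat.shape != shape:
                raise ValueError(f"{name} matrix has shape {mat.shape}, expected {shape}")
        if len(set(self.mutations)) != self.n_mutations:
            raise ValueError("mutation identifiers are not unique")
        if len(set(self.cells)) != self.n_cells:
            raise ValueError("cell identifiers are not unique")
        if np.any(self.depth < 0) or np.any(self.alt < 0):
            raise ValueError("negative read counts")
        bad = self.alt > self.depth
        if bad.any():
            x, c = np.argwhere(bad)[0]
            raise ValueError(
                f"alt exceeds depth at mutation {self.mutations[x]}, cell {self.cells[c]}"
            )
        covered = self.depth > 0
        if not np.all(np.isnan(self.vaf[~covered])):
            raise ValueError("VAF must be NaN (missing) where depth is 0")
        expect = np.zeros_like(self.vaf)
        np.divide(self.alt, self.depth, out=expect, where=covered)
        if not np.allclose(self.vaf[covered], expect[covered], atol=1e-6):
            raise ValueError("vaf != alt/depth on covered entries")

    def copy(self) -> "VafDataset":
        return replace(
            self,
            mutations=list(self.mutations),
            cells=list(self.cells),
            vaf=self.vaf.copy(),
            depth=self.depth.copy(),
            alt=self.alt.copy(),
            cell_annotations=dict(self.cell_annotations) if self.cell_annotations else None,
        )

    def subset_mutations(self, keep: "list[MutationId] | np.ndarray") -> "VafDataset":
        """Restrict to the given mutations (list of ids or boolean/index array)."""
        if isinstance(keep, np.ndarray):
            idx = np.flatnonzero(keep) if keep.dtype == bool else keep
        else:
            pos = {m: i for i, m in enumerate(self.mutations)}
            idx = np.array([pos[m] for m in keep], dtype=int)
        return replace(
            self,
            mutations=[self.mutations[i] for i in idx],
            vaf=self.vaf[idx],
            depth=self.depth[idx],
            alt=self.alt[idx],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, VafDataset):
            return NotImplemented
        return (
            self.mutations == other.mutations
            and self.cells == other.cells
            and np.array_equal(self.depth, other.depth)
            and np.array_equal(self.alt, other.alt)
            and np.allclose(self.vaf, other.vaf, atol=1e-12, equal_nan=True)
            and (self.cell_annotations or None) == (other.cell_annotations or None)
        )


def from_counts(
    mutations: list[MutationId],
    cells: list[str],
    alt: np.ndarray,
    depth: np.ndarray,
    cell_annotations: dict[str, str] | None = None,
) -> VafDataset:
    """Build a dataset from read counts, deriving VAF (NaN where depth 0)."""
    alt = np.asarray(alt, dtype=np.int64)
    depth = np.asarray(depth, dtype=np.int64)
    vaf = np.full(depth.shape, np.nan)
    np.divide(alt, depth, out=vaf, where=depth > 0)
    return VafDataset(mutations, cells, vaf, depth, alt, cell_annotations)


def _read_matrix(path, kind: str) -> pd.DataFrame:
    """Read one delimited matrix (or MTX triplet) with mutation-row index."""
    path = str(path)
    if path.endswith(".mtx"):
        from scipy.io import mmread

        mat = mmread(path)
        if hasattr(mat, "toarray"):
            mat = mat.toarray()
        mat = np.asarray(mat)
        rows = [l.strip() for l in open(path[:-4] + ".rows") if l.strip()]
        cols = [l.strip() for l in open(path[:-4] + ".cols") if l.strip()]
        df = pd.DataFrame(mat, index=rows, columns=cols)
    else:
        df = pd.read_csv(path, sep=None, engine="python", index_col=0)
        df.index = df.index.astype(str).str.strip()
        df.columns = [str(c).strip() for c in df.columns]
    if df.index.has_duplicates:
        raise ValueError(f"duplicate mutation identifiers in {kind} file {path}")
    return df


def read_vaf_dataset(
    vaf_path,
    depth_path,
    alt_path=None,
    annotation_path=None,
) -> VafDataset:
    """Load a VAF/depth(/alt) matrix set from delimited text.

    Rows and columns are aligned by identifier across files.  When no alt
    file is given, alt counts are reconstructed as ``round(vaf * depth)``.
    Entries with depth 0 are treated as missing regardless of the value
    stored in the VAF file.
    """
    vaf_df = _read_matrix(vaf_path, "vaf")
    depth_df = _read_matrix(depth_path, "depth")

    if set(vaf_df.index) != set(depth_df.index) or set(vaf_df.columns) != set(depth_df.columns):
        raise ValueError(
            f"identifier mismatch between {vaf_path} and depth file {depth_path}"
        )
    depth_df = depth_df.loc[vaf_df.index, vaf_df.columns]

    mutations = []
    for rownum, name in enumerate(vaf_df.index, start=2):  # header is line 1
        try:
            mutations.append(MutationId.parse(name))
        except ValueError as exc:
            raise ValueError(f"{vaf_path} line {rownum}: {exc}") from None

    cells = list(vaf_df.columns)
    depth = depth_df.to_numpy(dtype=np.int64)
    vaf = vaf_df.to_numpy(dtype=float)

    if alt_path is not None:
        alt_df = _read_matrix(alt_path, "alt")
        if set(alt_df.index) != set(vaf_df.index) or set(alt_df.columns) != set(vaf_df.columns):
            raise ValueError(f"identifier mismatch between {vaf_path} and alt file {alt_path}")
        alt = alt_df.loc[vaf_df.index, vaf_df.columns].to_numpy(dtype=np.int64)
    else:
        with np.errstate(invalid="ignore"):
            alt = np.round(np.nan_to_num(vaf) * depth).astype(np.int64)

    bad = alt > depth
    if bad.any():
        x, c = np.argwhere(bad)[0]
        raise ValueError(
            f"alt > depth at mutation {mutations[x]}, first offending cell {cells[c]}"
        )

    annotations = None
    if annotation_path is not None:
        ann = pd.read_csv(annotation_path, sep=None, engine="python", header=None, comment="#")
        if ann.iloc[0, 0] in ("cell", "Cell", "barcode"):
            ann = ann.iloc[1:]
        annotations = dict(zip(ann.iloc[:, 0].astype(str), ann.iloc[:, 1].astype(str)))

    vaf = vaf.copy()
    vaf[depth == 0] = np.nan
    # tolerate derived-vaf rounding: recompute from counts
    recomputed = np.full(vaf.shape, np.nan)
    np.divide(alt, depth, out=recomputed, where=depth > 0)
    if not np.allclose(vaf[depth > 0], recomputed[depth > 0], atol=1e-6):
        raise ValueError(f"VAF entries in {vaf_path} inconsistent with read counts")
    return VafDataset(mutations, cells, recomputed, depth, alt, annotations)


def write_vaf_dataset(ds: VafDataset, out_dir, prefix: str = "mt") -> dict[str, str]:
    """Write vaf/depth/alt (and annotation) CSVs; round-trips through read."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    names = ds.mutation_names
    paths = {}
    for kind, mat in (("vaf", ds.vaf), ("depth", ds.depth), ("alt", ds.alt)):
        df = pd.DataFrame(mat, index=names, columns=ds.cells)
        path = os.path.join(out_dir, f"{prefix}_{kind}.csv")
        df.to_csv(path, index_label="mutation", float_format="%.12g")
        paths[kind] = path
    if ds.cell_annotations:
        path = os.path.join(out_dir, f"{prefix}_annotations.csv")
        pd.DataFrame(
            {"cell": list(ds.cell_annotations), "label": list(ds.cell_annotations.values())}
        ).to_csv(path, index=False, header=False)
        paths["annotations"] = path
    return paths
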