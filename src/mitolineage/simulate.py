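"""Ground-truth clonal-tree simulator for single-cell MT mutation data.

The generator emulates a clonal expansion read out by single-cell
sequencing of the mitochondrial genome:

* A rooted clone tree.  By default the root spawns ``n_clones`` lineages,
  each a chain of ``n_levels`` successive generations (6 clones x 3
  generations = 18 branching events), mimicking sequential subcloning of
  a cell line.  Every time a parent produces a descendant the new edge
  acquires 1 + Poisson(lambda_clone) fresh clone-specific mutations, so
  every clone carries at least one private marker; with the defaults the
  expected clone-specific total is 18 x 2 = 36.  Each site mutates at
  most once anywhere (no parallel or back mutations) and heteroplasmy of
  each new mutation is drawn from Beta(a, b) (default Beta(2,5), VAF
  mass around 0.2, matching real mitochondrial somatic mutations).
* Cells are assigned uniformly at random to the tree's non-root nodes and
  inherit every clone-specific mutation on their root-to-node path at the
  edge's heteroplasmy.  The cell's clone label is the top-level lineage.
* Germline variants: Poisson(germline_lambda = 10) mutations with VAF
  drawn Uniform(0.5, 1), carried by each cell independently with
  probability germline_carrier_prob = 0.8.
* Cell-private somatic noise: Poisson(cell_private_lambda = 0.1) extra
  mutations per cell at Beta(a, b) heteroplasmy; these carry no lineage
  signal.
* Reads: for each mutation x cell, alt ~ Binomial(depth, q) with
  q = v(1-e) + (1-v)e/3, v the true heteroplasmy (0 in non-carriers),
  depth = 30 and e = 0.001 by default.

Everything is driven by one integer seed through numpy's Generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_matrix import MT_GENOME_LENGTH, MutationId, VafDataset, from_counts

_BASES = np.array(list("ACGT"))

CLONE_SPECIFIC = "clone_specific"
GERMLINE = "germline"
CELL_PRIVATE = "cell_private"


@dataclass(frozen=True)
class SimConfig:
    n_cells: int = 100
    n_clones: int = 6
    n_levels: int = 3
    lambda_clone: float = 1.0
    germline_lambda: float = 10.0
    germline_carrier_prob: float = 0.8
    germline_strict_fraction: bool = False
    cell_private_lambda: float = 0.1
    het_beta: tuple[float, float] = (2.0, 5.0)
    germline_vaf_range: tuple[float, float] = (0.5, 1.0)
    depth: int = 30
    poisson_depth: bool = False
    error_rate: float = 0.001
    genome_length: int = MT_GENOME_LENGTH
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clones < 2:
            raise ValueError("need at least 2 clones")
        for name in ("lambda_clone", "germline_lambda", "cell_private_lambda"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 < self.germline_carrier_prob <= 1:
            raise ValueError("germline_carrier_prob must be in (0, 1]")


@dataclass
class CloneTree:
    """Rooted clone tree with per-edge mutation placements.

    ``parent`` maps node -> parent node (root maps to None); each edge
    (parent, child) owns a list of (MutationId, heteroplasmy) pairs.
    ``clone_of`` maps node -> top-level clone label.
    """

    newick: str
    parent: dict[str, str | None]
    edge_mutations: dict[str, list[tuple[MutationId, float]]] = field(default_factory=dict)
    clone_of: dict[str, str] = field(default_factory=dict)

    @property
    def nodes(self) -> list[str]:
        return list(self.parent)

    def path_mutations(self, node: str) -> list[tuple[MutationId, float]]:
        out: list[tuple[MutationId, float]] = []
        while node is not None and self.parent.get(node) is not None:
            out = self.edge_mutations.get(node, []) + out
            node = self.parent[node]
        return out


@dataclass
class SimTruth:
    cell_clone: dict[str, str]
    cell_node: dict[str, str]
    mutation_class: dict[MutationId, str]
    true_vaf: np.ndarray  # mutations x cells
    mutations: list[MutationId] = field(default_factory=list)
    cells: list[str] = field(default_factory=list)

    def clone_specific_mutations(self) -> list[MutationId]:
        return [m for m, c in self.mutation_class.items() if c == CLONE_SPECIFIC]


def _draw_mutation(rng: np.random.Generator, used: set[int], genome_length: int) -> MutationId:
    if len(used) >= genome_length:
        raise RuntimeError("mitochondrial genome exhausted: no free positions left")
    while True:
        pos = int(rng.integers(1, genome_length + 1))
        if pos not in used:
            used.add(pos)
            break
    ref, alt = rng.choice(4, size=2, replace=False)
    return MutationId(pos, str(_BASES[ref]), str(_BASES[alt]))


def parse_newick_topology(newick: str) -> dict[str, str | None]:
    """Parent map from a user-supplied Newick string (topology only)."""
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")
    parent: dict[str, str | None] = {}
    counter = [0]

    def name_of(node) -> str:
        if node.taxon is not None and node.taxon.label:
            return node.taxon.label
        if node.label:
            return node.label
        counter[0] += 1
        node.label = f"node{counter[0]}"
        return node.label

    for node in tree.preorder_node_iter():
        name = name_of(node)
        parent[name] = name_of(node.parent_node) if node.parent_node else None
    return parent


def build_clone_tree(cfg: SimConfig = SimConfig(), newick: str | None = None) -> CloneTree:
    """Construct the clone tree and place clone-specific mutations on edges.

    The default topology has ``n_clones`` lineages of ``n_levels``
    generations each.  Every edge receives 1 + Poisson(lambda_clone)
    mutations at previously unused positions with Beta heteroplasmy.
    """
    rng = np.random.default_rng(cfg.seed)
    if newick is not None:
        parent = parse_newick_topology(newick)
        roots = [n for n, p in parent.items() if p is None]
        root = roots[0]
    else:
        root = "root"
        parent = {root: None}
        for c in range(1, cfg.n_clones + 1):
            prev = root
            for g in range(1, cfg.n_levels + 1):
                node = f"clone{c}_g{g}"
                parent[node] = prev
                prev = node

    clone_of: dict[str, str] = {}
    for node in parent:
        if parent[node] is None:
            continue
        top = node
        while parent[top] is not None and parent[parent[top]] is not None:
            top = parent[top]
        clone_of[node] = top

    used: set[int] = set()
    edge_mutations: dict[str, list[tuple[MutationId, float]]] = {}
    a, b = cfg.het_beta
    for node in parent:
        if parent[node] is None:
            continue
        n_mut = 1 + int(rng.poisson(cfg.lambda_clone))
        muts = []
        for _ in range(n_mut):
            mut = _draw_mutation(rng, used, cfg.genome_length)
            het = float(rng.beta(a, b))
            muts.append((mut, het))
        edge_mutations[node] = muts

    if newick is None:
        def nwk(node: str) -> str:
            children = [n for n, p in parent.items() if p == node]
            if not children:
                return node
            return "(" + ",".join(nwk(c) for c in children) + ")" + node

        newick = nwk(root) + ";"
    return CloneTree(newick=newick, parent=parent, edge_mutations=edge_mutations, clone_of=clone_of)


def assign_cells(tree: CloneTree, cfg: SimConfig = SimConfig()) -> SimTruth:
    """Assign cells to tree nodes and lay down true heteroplasmies.

    Cells go uniformly to non-root nodes and inherit all clone-specific
    mutations on their path; germline and cell-private mutations are
    added per the generator's model.  Positions never collide across
    mutation classes.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    nodes = [n for n in tree.parent if tree.parent[n] is not None]
    cells = [f"cell{i:04d}" for i in range(cfg.n_cells)]
    node_of = {c: nodes[int(rng.integers(len(nodes)))] for c in cells}
    cell_clone = {c: tree.clone_of[node_of[c]] for c in cells}

    used = {m.position for muts in tree.edge_mutations.values() for m, _ in muts}
    mutations: list[MutationId] = []
    mutation_class: dict[MutationId, str] = {}
    rows: list[np.ndarray] = []

    for node in tree.parent:
        for mut, het in tree.edge_mutations.get(node, []):
            mutations.append(mut)
            mutation_class[mut] = CLONE_SPECIFIC
            # carriers: cells at or below this edge's child node
            row = np.zeros(cfg.n_cells)
            for ci, c in enumerate(cells):
                anc = node_of[c]
                while anc is not None:
                    if anc == node:
                        row[ci] = het
                        break
                    anc = tree.parent[anc]
            rows.append(row)

    lo, hi = cfg.germline_vaf_range
    n_germline = int(rng.poisson(cfg.germline_lambda))
    for _ in range(n_germline):
        mut = _draw_mutation(rng, used, cfg.genome_length)
        mutation_class[mut] = GERMLINE
        mutations.append(mut)
        vaf = float(rng.uniform(lo, hi))
        if cfg.germline_strict_fraction:
            n_carriers = int(np.ceil(cfg.germline_carrier_prob * cfg.n_cells))
            carriers = np.zeros(cfg.n_cells, dtype=bool)
            carriers[rng.choice(cfg.n_cells, size=n_carriers, replace=False)] = True
        else:
            carriers = rng.random(cfg.n_cells) < cfg.germline_carrier_prob
        rows.append(np.where(carriers, vaf, 0.0))

    a, b = cfg.het_beta
    for ci, c in enumerate(cells):
        for _ in range(int(rng.poisson(cfg.cell_private_lambda))):
            mut = _draw_mutation(rng, used, cfg.genome_length)
            mutation_class[mut] = CELL_PRIVATE
            mutations.append(mut)
            row = np.zeros(cfg.n_cells)
            row[ci] = float(rng.beta(a, b))
            rows.append(row)

    true_vaf = np.vstack(rows) if rows else np.zeros((0, cfg.n_cells))
    return SimTruth(
        cell_clone=cell_clone,
        cell_node=node_of,
        mutation_class=mutation_class,
        true_vaf=true_vaf,
        mutations=mutations,
        cells=cells,
    )


def simulate_reads(truth: SimTruth, cfg: SimConfig = SimConfig()) -> VafDataset:
    """Binomial read-count model: alt ~ Binom(depth, v(1-e) + (1-v)e/3)."""
    rng = np.random.default_rng(cfg.seed + 2)
    v = truth.true_vaf
    e = cfg.error_rate
    q = v * (1.0 - e) + (1.0 - v) * e / 3.0
    if cfg.poisson_depth:
        depth = rng.poisson(cfg.depth, size=v.shape)
    else:
        depth = np.full(v.shape, cfg.depth, dtype=np.int64)
    alt = rng.binomial(depth, q)
    return from_counts(
        list(truth.mutations),
        list(truth.cells),
        alt,
        depth,
        cell_annotations=dict(truth.cell_clone),
    )


def simulate_dataset(cfg: SimConfig = SimConfig(), newick: str | None = None) -> tuple[VafDataset, SimTruth, CloneTree]:
    """Convenience: tree -> cell assignment -> reads, all from one seed."""
    tree = build_clone_tree(cfg, newick=newick)
    truth = assign_cells(tree, cfg)
    ds = simulate_reads(truth, cfg)
    return ds, truth, tree


def write_truth(truth: SimTruth, out_prefix: str) -> dict[str, str]:
    """Write cell->clone, mutation-class and true-VAF tables as CSV."""
    import pandas as pd

    paths = {}
    paths["cells"] = f"{out_prefix}_cell_clones.csv"
    pd.DataFrame(
        {
            "cell": list(truth.cells),
            "clone": [truth.cell_clone[c] for c in truth.cells],
            "node": [truth.cell_node[c] for c in truth.cells],
        }
    ).to_csv(paths["cells"], index=False)

    paths["classes"] = f"{out_prefix}_mutation_classes.csv"
    pd.DataFrame(
        {
            "mutation": [str(m) for m in truth.mutations],
            "class": [truth.mutation_class[m] for m in truth.mutations],
        }
    ).to_csv(paths["classes"], index=False)

    paths["true_vaf"] = f"{out_prefix}_true_vaf.csv"
    pd.DataFrame(truth.true_vaf, index=[str(m) for m in truth.mutations], columns=truth.cells).to_csv(
        paths["true_vaf"], index_label="mutation", float_format="%.12g"
    )
    return paths


def read_truth(out_prefix: str) -> SimTruth:
    """Inverse of write_truth."""
    import pandas as pd

    cells_df = pd.read_csv(f"{out_prefix}_cell_clones.csv")
    classes_df = pd.read_csv(f"{out_prefix}_mutation_classes.csv")
    vaf_df = pd.read_csv(f"{out_prefix}_true_vaf.csv", index_col=0)
    mutations = [MutationId.parse(m) for m in classes_df["mutation"]]
    return SimTruth(
        cell_clone=dict(zip(cells_df["cell"], cells_df["clone"])),
        cell_node=dict(zip(cells_df["cell"], cells_df["node"])),
        mutation_class=dict(zip(mutations, classes_df["class"])),
        true_vaf=vaf_df.to_numpy(dtype=float),
        mutations=mutations,
        cells=list(cells_df["cell"]),
    )
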