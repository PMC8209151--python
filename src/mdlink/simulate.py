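"""Seeded synthetic inputs with planted block structure.

Every pipeline input — miRNA sequences, a MeSH-style tree-number table, the
nine association edge lists and the positive-pair list — is generated from
one :class:`FixtureSpec` and a seed, with a known planted signal:

* nodes of every type are assigned to ``n_blocks`` blocks;
* miRNA-disease edges appear with probability ``p_in`` within matched
  blocks and ``p_out`` across blocks (``p_in > p_out`` is the recoverable
  signal; setting them equal gives a null fixture);
* miRNAs of a block share an embedded 6-mer motif, so sequence-derived
  attribute features also carry block identity;
* each block's diseases live under a private branch of the tree-number
  hierarchy, so semantic similarity is higher within blocks;
* the other eight association types are sampled with the same within/
  between block densities scaled to ``other_density``.

Outputs are pure functions of (spec, seed): the same spec always produces
byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .network import ASSOC_TYPES, EdgeRecord, HeteroNetwork, LabeledPairSet, NodeRef, assemble_network

_BASES = np.array(list("ACGU"))


@dataclass(frozen=True)
class FixtureSpec:
    """Stated world of the synthetic fixtures (defaults are the test scale)."""

    n_mirna: int = 60
    n_disease: int = 40
    n_protein: int = 50
    n_lncrna: int = 30
    n_drug: int = 30
    n_blocks: int = 3
    p_in: float = 0.3
    p_out: float = 0.02
    other_density: float = 0.08
    other_density_out: float = 0.01
    seq_len_range: tuple[int, int] = (20, 25)
    motif_len: int = 6
    dag_depth: int = 3
    dag_branching: int = 3
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.p_out <= self.p_in <= 1):
            raise ValueError("need 0 <= p_out <= p_in <= 1")
        if min(self.n_mirna, self.n_disease) < self.n_blocks:
            raise ValueError("fewer miRNAs/diseases than blocks")
        if min(self.n_protein, self.n_lncrna, self.n_drug) < 1:
            raise ValueError("every node type needs at least one node")

    def counts(self) -> dict[str, int]:
        return {
            "miRNA": self.n_mirna, "disease": self.n_disease,
            "protein": self.n_protein, "lncRNA": self.n_lncrna,
            "drug": self.n_drug,
        }


def _block_of(i: int, n: int, n_blocks: int) -> int:
    """Contiguous block assignment of node i among n nodes."""
    return min(i * n_blocks // n, n_blocks - 1)


def node_ids(spec: FixtureSpec) -> dict[str, list[str]]:
    """Deterministic node identifiers per type."""
    prefix = {"miRNA": "mi", "disease": "di", "protein": "pr",
              "lncRNA": "ln", "drug": "dr"}
    return {
        t: [f"{prefix[t]}{i:03d}" for i in range(n)]
        for t, n in spec.counts().items()
    }


def block_assignment(spec: FixtureSpec) -> dict[tuple[str, str], int]:
    """Block index of every node, keyed by (node_type, node_id)."""
    out = {}
    for t, ids in node_ids(spec).items():
        for i, nid in enumerate(ids):
            out[(t, nid)] = _block_of(i, len(ids), spec.n_blocks)
    return out


def _block_motifs(spec: FixtureSpec, rng: np.random.Generator) -> list[str]:
    """Distinct per-block sequence motifs."""
    motifs: list[str] = []
    while len(motifs) < spec.n_blocks:
        m = "".join(rng.choice(_BASES, size=spec.motif_len))
        if m not in motifs:
            motifs.append(m)
    return motifs


def generate_sequences(spec: FixtureSpec) -> dict[str, str]:
    """Random 20-25 nt miRNA sequences with a planted per-block motif."""
    rng = np.random.default_rng(spec.seed)
    motifs = _block_motifs(spec, rng)
    lo, hi = spec.seq_len_range
    seqs: dict[str, str] = {}
    for i, mid in enumerate(node_ids(spec)["miRNA"]):
        length = int(rng.integers(lo, hi + 1))
        seq = list(rng.choice(_BASES, size=length))
        motif = motifs[_block_of(i, spec.n_mirna, spec.n_blocks)]
        pos = int(rng.integers(0, length - spec.motif_len + 1))
        seq[pos : pos + spec.motif_len] = list(motif)
        seqs[mid] = "".join(seq)
    return seqs


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=k, description="") for k, s in sorted(seqs.items())]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {r.id: str(r.seq) for r in SeqIO.parse(str(path), "fasta")}


def generate_mesh_table(spec: FixtureSpec) -> dict[str, list[str]]:
    """Tree numbers placing each block's diseases under a private branch.

    Block b owns the top-level category ``C{b+1:02d}``; within it, diseases
    sit at depth 2..dag_depth+1 on branches drawn from ``dag_branching``
    children per level, so same-block diseases share ancestors and
    cross-block diseases share none.
    """
    rng = np.random.default_rng(spec.seed + 1)
    table: dict[str, list[str]] = {}
    for i, did in enumerate(node_ids(spec)["disease"]):
        b = _block_of(i, spec.n_disease, spec.n_blocks)
        depth = int(rng.integers(1, spec.dag_depth + 1))
        parts = [f"C{b + 1:02d}"]
        for _ in range(depth):
            parts.append(f"{int(rng.integers(1, spec.dag_branching + 1)) * 100}")
        table[did] = [".".join(parts)]
        # occasionally give a second, shallower number on the same branch
        if rng.random() < 0.3 and depth >= 2:
            parts2 = parts[:-1]
            parts2[-1] = f"{int(rng.integers(1, spec.dag_branching + 1)) * 100}"
            num2 = ".".join(parts2)
            if num2 != table[did][0]:
                table[did].append(num2)
    return table


def write_mesh_table(table: dict[str, list[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# disease_id\ttree_number\n")
        for did in sorted(table):
            for num in table[did]:
                fh.write(f"{did}\t{num}\n")


def _sample_pairs(
    ids_a: list[str], ids_b: list[str], type_a: str, type_b: str,
    blocks: dict[tuple[str, str], int],
    p_same: float, p_diff: float, rng: np.random.Generator,
) -> list[tuple[str, str]]:
    """Bernoulli edge sampling with block-dependent probability."""
    edges = []
    same_type = type_a == type_b
    for i, a in enumerate(ids_a):
        for j, b in enumerate(ids_b):
            if same_type and j <= i:  # undirected, no self-loops
                continue
            p = p_same if blocks[(type_a, a)] == blocks[(type_b, b)] else p_diff
            if rng.random() < p:
                edges.append((a, b))
    return edges


@dataclass
class Fixture:
    """In-memory bundle of one generated world."""

    spec: FixtureSpec
    network: HeteroNetwork
    sequences: dict[str, str]
    mesh_table: dict[str, list[str]]
    positives: LabeledPairSet
    edge_lists: dict[str, list[tuple[str, str]]] = field(default_factory=dict)


def generate_network(spec: FixtureSpec) -> Fixture:
    """Sample the full heterogeneous network plus the positive-pair list.

    The miRNA-disease edges double as the positive labels; the remaining
    eight association types get ``other_density`` within blocks and
    ``other_density_out`` across, giving behaviour features block signal of
    their own.
    """
    rng = np.random.default_rng(spec.seed + 2)
    ids = node_ids(spec)
    blocks = block_assignment(spec)
    edge_lists: dict[str, list[tuple[str, str]]] = {}
    for assoc in sorted(ASSOC_TYPES):
        ta, tb = ASSOC_TYPES[assoc]
        if assoc == "miRNA-disease":
            p_same, p_diff = spec.p_in, spec.p_out
        else:
            p_same, p_diff = spec.other_density, spec.other_density_out
        edge_lists[assoc] = _sample_pairs(
            ids[ta], ids[tb], ta, tb, blocks, p_same, p_diff, rng
        )
    records = [
        EdgeRecord(NodeRef(ASSOC_TYPES[a][0], s), NodeRef(ASSOC_TYPES[a][1], t), a)
        for a, pairs in edge_lists.items()
        for s, t in pairs
    ]
    # isolated nodes still belong to the network: add zero-degree nodes
    all_nodes = {NodeRef(t, nid) for t, lst in ids.items() for nid in lst}
    net = assemble_network(records)
    missing = sorted(all_nodes - set(net.nodes))
    if missing:
        nodes = tuple(sorted(all_nodes))
        idx = {n: i for i, n in enumerate(nodes)}
        s = np.zeros((len(nodes), len(nodes)), dtype=np.uint8)
        for e in records:
            i, j = idx[e.source], idx[e.target]
            s[i, j] = s[j, i] = 1
        net = HeteroNetwork(nodes=nodes, adjacency=s)
    positives = LabeledPairSet(
        tuple((m, d, 1) for m, d in sorted(edge_lists["miRNA-disease"]))
    )
    if len(positives) < 5:
        raise ValueError(
            "degenerate spec: fewer than 5 positive miRNA-disease pairs"
        )
    return Fixture(
        spec=spec,
        network=net,
        sequences=generate_sequences(spec),
        mesh_table=generate_mesh_table(spec),
        positives=positives,
        edge_lists=edge_lists,
    )


def write_fixture(fix: Fixture, out_dir: str | Path) -> dict[str, Path]:
    """Write FASTA, MeSH TSV, per-association edge TSVs and positives TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["fasta"] = out / "mirna_sequences.fasta"
    write_fasta(fix.sequences, paths["fasta"])
    paths["mesh"] = out / "disease_mesh.tsv"
    write_mesh_table(fix.mesh_table, paths["mesh"])
    for assoc, pairs in fix.edge_lists.items():
        p = out / f"edges_{assoc.replace('-', '_')}.tsv"
        with open(p, "w") as fh:
            fh.write("# source_id\ttarget_id\n")
            for a, b in sorted(pairs):
                fh.write(f"{a}\t{b}\n")
        paths[assoc] = p
    paths["positives"] = out / "positive_pairs.tsv"
    fix.positives.to_file(paths["positives"])
    return paths
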