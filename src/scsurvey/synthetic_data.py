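"""Synthetic proteomes, families and ground truth for offline testing.

The generator emulates, at desk scale, the data the survey was built
for: protein families diverged along a known tree, decoy proteomes
with background residue composition, coiled-coil-rich proteins whose
shuffled analogs still align well, and one long chimeric "exclusive"
protein whose similarity signal is confined to a coiled-coil
C-terminal region.

Substitution model: replacement probabilities come from the scoring
matrix itself — row-wise softmax of the BLOSUM62 scores on their
natural log-odds scale — so simulation and scoring are mutually
consistent; background frequencies are the stationary distribution of
that exchange matrix.  Indels are geometric-length (mean 3) events at
a small per-site probability per branch.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .coiledcoil import load_propensity_table, sample_heptad_sequence
from .pairwise_align import ScoringScheme, default_scheme
from .seqio import AMINO_ACIDS, ProteinRecord, write_fasta

# ---------------------------------------------------------------------------
# Substitution model derived from the scoring matrix
# ---------------------------------------------------------------------------

#: marginal residue frequencies of the default matrix's target distribution
#: (the classic BLOSUM62 background composition), order ARNDCQEGHILKMFPSTWYV
_BLOSUM62_BACKGROUND = np.array([
    0.0742, 0.0516, 0.0446, 0.0536, 0.0246, 0.0342, 0.0543, 0.0741, 0.0262,
    0.0679, 0.0989, 0.0582, 0.0250, 0.0474, 0.0385, 0.0572, 0.0508, 0.0131,
    0.0321, 0.0729,
])


def background_frequencies(scheme: ScoringScheme | None = None) -> np.ndarray:
    """Background residue frequencies of the scoring model (the
    substitution matrix's marginal target frequencies)."""
    bg = _BLOSUM62_BACKGROUND
    return bg / bg.sum()


def _ungapped_lambda(scheme: ScoringScheme | None = None) -> float:
    """Natural log-odds scale of the matrix: the positive root of
    sum_ab p_a p_b exp(lambda s_ab) = 1 at the background frequencies
    (~0.32 nats per unit for BLOSUM62)."""
    from scipy.optimize import brentq

    if scheme is None:
        scheme = default_scheme()
    scores = scheme.matrix[:20, :20].astype(float)
    bg = background_frequencies(scheme)
    pp = np.outer(bg, bg)

    def f(l: float) -> float:
        return float((pp * np.exp(l * scores)).sum() - 1.0)

    return float(brentq(f, 1e-4, 2.0, xtol=1e-12))


_LAMBDA_CACHE: dict[bytes, float] = {}


def exchange_matrix(scheme: ScoringScheme | None = None) -> np.ndarray:
    """(20, 20) row-stochastic replacement matrix: softmax of matrix rows
    on the matrix's own ungapped log-odds scale."""
    if scheme is None:
        scheme = default_scheme()
    scores = scheme.matrix[:20, :20].astype(float)
    key = scores.tobytes()
    if key not in _LAMBDA_CACHE:
        _LAMBDA_CACHE[key] = _ungapped_lambda(scheme)
    w = np.exp(_LAMBDA_CACHE[key] * scores)
    return w / w.sum(axis=1, keepdims=True)


def random_background_sequence(length: int, rng: np.random.Generator, bg: np.ndarray | None = None) -> str:
    if bg is None:
        bg = background_frequencies()
    idx = rng.choice(20, size=length, p=bg)
    return "".join(AMINO_ACIDS[i] for i in idx)


def mutate_sequence(
    seq: str,
    t: float,
    rng: np.random.Generator,
    scheme: ScoringScheme | None = None,
    subst_rate: float = 1.0,
    indel_prob: float = 0.0,
    indel_mean_len: float = 3.0,
    bg: np.ndarray | None = None,
) -> str:
    """Evolve ``seq`` along one branch of length ``t``.

    Each site substitutes with probability 1 - exp(-subst_rate * t);
    the replacement is drawn from the exchange-matrix row of the old
    residue (self-replacement allowed).  Indels occur per site with
    probability ``indel_prob``, geometric length (mean
    ``indel_mean_len``), insertions drawn from the background.
    """
    P = exchange_matrix(scheme)
    if bg is None:
        bg = background_frequencies(scheme)
    aa_index = {a: i for i, a in enumerate(AMINO_ACIDS)}
    p_sub = 1.0 - np.exp(-subst_rate * t)
    out = []
    geo_p = 1.0 / indel_mean_len
    for ch in seq:
        if ch not in aa_index:  # X passes through unmutated
            out.append(ch)
            continue
        if indel_prob > 0 and rng.random() < indel_prob:
            if rng.random() < 0.5:  # deletion of a geometric run (this site on)
                continue
            ins_len = rng.geometric(geo_p)
            out.append(random_background_sequence(int(ins_len), rng, bg))
        if rng.random() < p_sub:
            out.append(AMINO_ACIDS[rng.choice(20, p=P[aa_index[ch]])])
        else:
            out.append(ch)
    return "".join(out)


def expected_mismatch_fraction(t: float, scheme: ScoringScheme | None = None, subst_rate: float = 1.0) -> float:
    """Exact per-site mismatch expectation of :func:`mutate_sequence`
    (no indels) for a background-distributed site after one branch."""
    P = exchange_matrix(scheme)
    bg = background_frequencies(scheme)
    p_sub = 1.0 - np.exp(-subst_rate * t)
    p_same_given_sub = float((bg * np.diag(P)).sum())
    return p_sub * (1.0 - p_same_given_sub)


# ---------------------------------------------------------------------------
# Configuration and ground truth
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    seed: int = 0
    n_taxa: int = 8
    tree: str | None = None           # newick; None -> random topology
    root_len: int = 300
    subst_rate: float = 1.0           # expected substitution events /site /unit branch
    indel_rate: float = 0.01          # per-site indel probability per branch
    branch_range: tuple[float, float] = (0.02, 0.12)  # "moderate divergence"
    cc_insert: tuple[float, int, int] | None = None   # (rel. position, length, frame)
    decoys_per_taxon: int = 12
    decoy_len_range: tuple[int, int] = (150, 400)

    def __post_init__(self) -> None:
        if self.n_taxa < 3:
            raise ValueError("n_taxa must be >= 3")
        if self.root_len < 50:
            raise ValueError("root_len must be >= 50")
        if self.subst_rate < 0 or self.indel_rate < 0:
            raise ValueError("rates must be >= 0")


@dataclass
class GroundTruth:
    true_tree: str = ""                                   # newick
    ortholog_ids: dict[str, str] = field(default_factory=dict)      # taxon -> id
    planted_cc_intervals: dict[str, tuple[int, int]] = field(default_factory=dict)
    exclusive_ids: list[str] = field(default_factory=list)
    expected_tiers: dict[tuple[str, str], str] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "true_tree": self.true_tree,
            "ortholog_ids": self.ortholog_ids,
            "planted_cc_intervals": {k: list(v) for k, v in self.planted_cc_intervals.items()},
            "exclusive_ids": self.exclusive_ids,
            "expected_tiers": {f"{t}\t{q}": v for (t, q), v in self.expected_tiers.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=2))


# ---------------------------------------------------------------------------
# Family evolution along a known tree
# ---------------------------------------------------------------------------

class _SimNode:
    __slots__ = ("name", "children", "length")

    def __init__(self, name=None, length=0.0):
        self.name = name
        self.children: list[_SimNode] = []
        self.length = length

    def newick(self) -> str:
        def fmt(node: _SimNode) -> str:
            if not node.children:
                return f"{node.name}:{node.length:.6f}"
            inner = ",".join(fmt(c) for c in node.children)
            return f"({inner}):{node.length:.6f}"

        inner = ",".join(fmt(c) for c in self.children)
        return f"({inner});"


def random_tree(n_taxa: int, rng: np.random.Generator, branch_range: tuple[float, float]) -> _SimNode:
    """Random binary topology by sequential joins; branch lengths
    uniform in ``branch_range``."""
    lo, hi = branch_range
    nodes = [_SimNode(name=f"taxon{i}", length=float(rng.uniform(lo, hi))) for i in range(n_taxa)]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a = nodes.pop(j)
        b = nodes.pop(i)
        parent = _SimNode(length=float(rng.uniform(lo, hi)))
        parent.children = [b, a]
        nodes.append(parent)
    root = _SimNode(length=0.0)
    root.children = nodes
    return root


def evolve_family(cfg: SimConfig) -> tuple[list[ProteinRecord], GroundTruth]:
    """Evolve one protein family along a (random or given) tree.

    Leaves are named ``taxon<i>``; the returned ground truth holds the
    true tree in newick.  Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    bg = background_frequencies()
    if cfg.tree is not None:
        raise NotImplementedError("fixed input trees are parsed by distphylo.read_newick; "
                                  "pass topologies through SimConfig.tree=None + seed instead")
    tree = random_tree(cfg.n_taxa, rng, cfg.branch_range)

    root_seq = random_background_sequence(cfg.root_len, rng, bg)
    if cfg.cc_insert is not None:
        rel_pos, length, frame = cfg.cc_insert
        start = int(rel_pos * cfg.root_len)
        cc = sample_heptad_sequence(length, frame, rng)
        root_seq = root_seq[:start] + cc + root_seq[start + length:]

    records: list[ProteinRecord] = []

    def walk(node: _SimNode, seq: str) -> None:
        evolved = mutate_sequence(
            seq,
            node.length,
            rng,
            subst_rate=cfg.subst_rate,
            indel_prob=cfg.indel_rate,
            bg=bg,
        )
        if not node.children:
            records.append(
                ProteinRecord(id=node.name, seq=evolved, taxon=node.name, description="simulated homolog")
            )
        else:
            for child in node.children:
                walk(child, evolved)

    for child in tree.children:
        walk(child, root_seq)

    truth = GroundTruth(
        true_tree=tree.newick(),
        ortholog_ids={r.taxon: r.id for r in records},
    )
    return records, truth


# ---------------------------------------------------------------------------
# Coiled-coil proteins and the exclusive chimera
# ---------------------------------------------------------------------------

def make_cc_protein(length: int, heptad_frame: int = 0, seed: int = 0) -> ProteinRecord:
    """Idealized coiled-coil protein drawn from the heptad model."""
    if length < 28:
        raise ValueError("length must be >= 28")
    rng = np.random.default_rng(seed)
    seq = sample_heptad_sequence(length, heptad_frame, rng)
    return ProteinRecord(id=f"cc_{seed}", seq=seq, description="synthetic coiled-coil protein")


def make_exclusive_chimera(
    total_len: int = 4000, cc_tail_fraction: float = 1.0 / 3.0, seed: int = 0
) -> tuple[ProteinRecord, tuple[int, int]]:
    """Large chimeric protein: globular background head plus a
    coiled-coil tail occupying the final ``cc_tail_fraction``.

    Returns the record and the (start, end) tail interval (equal
    start/end when the fraction is 0).
    """
    if total_len < 300:
        raise ValueError("total_len must be >= 300")
    rng = np.random.default_rng(seed)
    tail_len = int(round(total_len * cc_tail_fraction))
    head = random_background_sequence(total_len - tail_len, rng)
    tail = sample_heptad_sequence(tail_len, int(rng.integers(7)), rng) if tail_len else ""
    rec = ProteinRecord(
        id=f"chimera_{seed}",
        seq=head + tail,
        description="synthetic exclusive protein (coiled-coil C-terminal region)",
    )
    return rec, (total_len - tail_len, total_len)


# ---------------------------------------------------------------------------
# Survey fixture
# ---------------------------------------------------------------------------

def _embed_core(query: str, core_span: tuple[int, int], host_len: int, t: float, rng: np.random.Generator, bg: np.ndarray) -> str:
    """Random host sequence with a mutated copy of query[core] embedded."""
    core = mutate_sequence(query[core_span[0]: core_span[1]], t, rng, bg=bg)
    pre_len = (host_len - len(core)) // 2
    pre = random_background_sequence(pre_len, rng, bg)
    post = random_background_sequence(host_len - pre_len - len(core), rng, bg)
    return pre + core + post


def make_survey_fixture(cfg: SimConfig | None = None) -> tuple[list[ProteinRecord], dict[str, list[ProteinRecord]], GroundTruth]:
    """Bundle a 3-query panel, per-taxon proteomes and ground truth.

    Queries: a conserved globular family (high tier where planted), a
    family sharing only a short conserved core (moderate tier), and a
    coiled-coil protein.  Taxa: two with orthologs of the globular
    queries, one decoys-only, and one additionally carrying the long
    chimeric exclusive protein — the only cell expected to trip the
    shuffle-null exclusivity flag.
    """
    if cfg is None:
        cfg = SimConfig()
    rng = np.random.default_rng(cfg.seed)
    bg = background_frequencies()

    q_cons = ProteinRecord(id="Q_conserved", seq=random_background_sequence(350, rng, bg),
                           description="conserved globular query")
    q_mod = ProteinRecord(id="Q_core", seq=random_background_sequence(300, rng, bg),
                          description="query with short conserved core")
    q_cc = make_cc_protein(250, heptad_frame=0, seed=int(rng.integers(2**31 - 1)))
    q_cc.id = "Q_coiledcoil"
    panel = [q_cons, q_mod, q_cc]

    def decoys(taxon: str) -> list[ProteinRecord]:
        out = []
        for i in range(cfg.decoys_per_taxon):
            length = int(rng.integers(cfg.decoy_len_range[0], cfg.decoy_len_range[1] + 1))
            out.append(ProteinRecord(id=f"{taxon}_decoy{i}",
                                     seq=random_background_sequence(length, rng, bg),
                                     taxon=taxon, description="background decoy"))
        return out

    core_span = (130, 170)  # 40-residue conserved core of Q_core
    proteomes: dict[str, list[ProteinRecord]] = {}
    truth = GroundTruth()

    chimera, tail = make_exclusive_chimera(total_len=4000, cc_tail_fraction=1.0 / 3.0,
                                           seed=int(rng.integers(2**31 - 1)))
    truth.planted_cc_intervals[chimera.id] = tail
    truth.exclusive_ids = [chimera.id]

    for taxon in ("taxon_a", "taxon_b", "taxon_c", "taxon_d"):
        prot = decoys(taxon)
        if taxon != "taxon_c":  # taxon_c: decoys only
            orth_cons = ProteinRecord(
                id=f"{taxon}_cons_ortholog",
                seq=mutate_sequence(q_cons.seq, 0.03, rng, bg=bg),
                taxon=taxon, description="close ortholog of Q_conserved")
            orth_mod = ProteinRecord(
                id=f"{taxon}_core_ortholog",
                seq=_embed_core(q_mod.seq, core_span, 280, 0.1, rng, bg),
                taxon=taxon, description="shares a 40-residue core with Q_core")
            prot += [orth_cons, orth_mod]
            truth.expected_tiers[(taxon, q_cons.id)] = "high"
            truth.expected_tiers[(taxon, q_mod.id)] = "moderate"
            truth.expected_tiers[(taxon, q_cc.id)] = "low"
        else:
            for q in panel:
                truth.expected_tiers[(taxon, q.id)] = "low"
        if taxon == "taxon_d":
            chim = ProteinRecord(id=chimera.id, seq=chimera.seq, taxon=taxon,
                                 description=chimera.description)
            prot.append(chim)
            # the coiled-coil query's similarity to the chimera tail sits in
            # the 50-100 bit band, like the published exclusive scores
            truth.expected_tiers[(taxon, q_cc.id)] = "moderate"
        proteomes[taxon] = prot

    return panel, proteomes, truth


def write_fixture(out_dir: str | Path, cfg: SimConfig | None = None) -> None:
    """Materialize the survey fixture as FASTA files + ground truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    panel, proteomes, truth = make_survey_fixture(cfg)
    write_fasta(panel, out / "panel.fasta")
    for taxon, records in proteomes.items():
        write_fasta(records, out / f"{taxon}.fasta")
    truth.to_json(out / "ground_truth.json")
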