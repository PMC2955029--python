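"""Generators for synthetic host/intron datasets.

The generators emulate the statistical structure the co-phylogeny analysis
assumes: a Yule host tree; an intron ("parasite") lineage that tracks host
lineages, duplicating at host speciations, with optional Poisson host-switch
(horizontal transfer) and loss events; nucleotide alignments evolved on each
tree under a reversible substitution model; and cox1-like coding sequences
with introns inserted after a chosen reference position.  With switch and
loss rates zero the intron tree is topologically identical to the host tree
(pure co-divergence); host switches move an intron to a contemporaneous
random other host lineage, displacing any resident intron, which is the
event-level counterpart of homing-endonuclease-driven transfer.

Every generator takes an explicit seed (or ``numpy`` Generator); the streams
are integer-based at all decision points, so runs are reproducible across
platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .formats_io import (GeneticCode, MultipleAlignment, SequenceRecord,
                         TABLE_4, translate)
from .phylo_core.model import SubstModel
from .phylo_core.tree import Node, PhyloTree

_STATES = "ACGT"

#: one codon per residue of the conserved homing-endonuclease motif
_LAGLIDADG_CODONS = ["TTA", "GCT", "GGT", "TTA", "ATT", "GAT", "GCT", "GAT", "GGT"]
_TABLE4_STOPS = {"TAA", "TAG"}


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

def simulate_host_tree(n: int, birth_rate: float = 1.0,
                       seed: int | np.random.Generator = 0) -> PhyloTree:
    """Yule (pure-birth) tree with ``n`` leaves, branch lengths in time units.

    Lineages split at rate ``birth_rate`` each; the tree is extended past the
    n-th speciation by one more waiting time so terminal branches are not
    zero.  Leaves are labelled h1..hn in order of creation.
    """
    if n < 3:
        raise ValueError(f"need n >= 3 leaves, got {n}")
    rng = _rng(seed)
    root = Node()
    t = 0.0
    # root split starts two lineages at time 0
    active: list[tuple[Node, float]] = []
    for _ in range(2):
        c = root.add(Node())
        active.append((c, 0.0))
    while len(active) < n:
        k = len(active)
        t += rng.exponential(1.0 / (birth_rate * k))
        i = int(rng.integers(k))
        node, born = active.pop(i)
        node.length = t - born
        for _ in range(2):
            c = node.add(Node())
            active.append((c, t))
    t_end = t + rng.exponential(1.0 / (birth_rate * n))
    for node, born in active:
        node.length = t_end - born
    tree = PhyloTree(root)
    # labels assigned by a random permutation so leaf names are exchangeable
    order = rng.permutation(n) + 1
    for i, leaf in enumerate(tree.leaves()):
        leaf.label = f"h{order[i]}"
    return tree


@dataclass
class CophyloScenario:
    """A host tree, its tracked parasite (intron) tree, and their links."""

    host_tree: PhyloTree
    parasite_tree: PhyloTree
    links: list[tuple[str, str]]  # (host leaf, parasite leaf) pairs
    events: list[dict] = field(default_factory=list)

    @property
    def n_switches(self) -> int:
        return sum(1 for e in self.events if e["type"] == "host_switch")


class _Lineage:
    __slots__ = ("parent_pnode", "start_time", "host")

    def __init__(self, parent_pnode: Node, start_time: float, host: Node) -> None:
        self.parent_pnode = parent_pnode  # parasite node this branch descends from
        self.start_time = start_time
        self.host = host  # host node terminating the tracked host edge


def simulate_cophylogeny(host_tree: PhyloTree, switch_rate: float = 0.0,
                         loss_rate: float = 0.0,
                         seed: int | np.random.Generator = 0,
                         n_switches: Optional[int] = None,
                         forced_switches: Optional[Sequence[tuple]] = None
                         ) -> CophyloScenario:
    """Track a parasite over ``host_tree`` with switch and loss events.

    ``n_switches`` overrides ``switch_rate`` with an exact number of switch
    events at times drawn uniformly over the host tree's depth (useful for
    fixed-effect-size power studies).  ``forced_switches`` is a list of
    ``(time, donor_leaf, recipient_leaf)`` tuples: at ``time`` the parasite on
    the host lineage ancestral to ``donor_leaf`` moves to the lineage
    ancestral to ``recipient_leaf`` (either may be None for a random choice).
    Raises if every parasite is lost.
    """
    rng = _rng(seed)
    host = host_tree.copy()
    # absolute times
    time_of: dict[int, float] = {id(host.root): 0.0}
    for node in host.preorder():
        if node.parent is not None:
            time_of[id(node)] = time_of[id(node.parent)] + node.length
    depth = max(time_of[id(l)] for l in host.leaves())

    forced: list[tuple] = []
    if forced_switches is not None:
        forced = sorted(forced_switches, key=lambda e: e[0])
        switch_rate = 0.0
    elif n_switches is not None:
        forced = [(t_, None, None)
                  for t_ in sorted(rng.uniform(0.0, depth, size=n_switches))]
        switch_rate = 0.0

    proot = Node()
    lineages: list[_Lineage] = [
        _Lineage(proot, 0.0, c) for c in host.root.children
    ]
    events: list[dict] = []
    t = 0.0

    def alive_edges(at: float) -> list[Node]:
        out = []
        for node in host.preorder():
            if node.parent is None:
                continue
            lo = time_of[id(node.parent)]
            hi = time_of[id(node)]
            if lo < at <= hi:
                out.append(node)
        return out

    def lineage_toward(leaf_label: str, at: float) -> Optional[Node]:
        """Host edge alive at ``at`` on the root path to ``leaf_label``."""
        leaf = next((l for l in host.leaves() if l.label == leaf_label), None)
        if leaf is None:
            raise ValueError(f"unknown host leaf {leaf_label!r}")
        chain = []
        n = leaf
        while n.parent is not None:
            chain.append(n)
            n = n.parent
        for n in reversed(chain):
            if time_of[id(n.parent)] < at <= time_of[id(n)]:
                return n
        return None

    def do_switch(at: float, donor: Optional[str] = None,
                  recipient: Optional[str] = None) -> None:
        if not lineages:
            return
        if donor is not None:
            edge = lineage_toward(donor, at)
            lin = next((l for l in lineages if l.host is edge), None)
            if lin is None:
                return  # no parasite on the requested donor lineage
        else:
            lin = lineages[int(rng.integers(len(lineages)))]
        targets = [e for e in alive_edges(at) if e is not lin.host]
        if not targets:
            return
        if recipient is not None:
            target = lineage_toward(recipient, at)
            if target is None or target is lin.host:
                return
        else:
            target = targets[int(rng.integers(len(targets)))]
        resident = next((l for l in lineages if l.host is target), None)
        if resident is not None:
            lineages.remove(resident)
            events.append({"type": "loss", "time": at,
                           "donor": _edge_name(resident.host), "recipient": None,
                           "cause": "displaced"})
        events.append({"type": "host_switch", "time": at,
                       "donor": _edge_name(lin.host),
                       "recipient": _edge_name(target)})
        lin.host = target

    while lineages:
        next_host_t = min(time_of[id(l.host)] for l in lineages)
        rate = len(lineages) * (switch_rate + loss_rate)
        t_stoch = t + rng.exponential(1.0 / rate) if rate > 0 else np.inf
        t_forced = forced[0][0] if forced else np.inf
        if t_forced <= min(next_host_t, t_stoch):
            _, donor, recipient = forced.pop(0)
            t = t_forced
            do_switch(t, donor, recipient)
            continue
        if t_stoch < next_host_t:
            t = t_stoch
            lin = lineages[int(rng.integers(len(lineages)))]
            if rng.random() < switch_rate / (switch_rate + loss_rate):
                do_switch(t)
            else:
                lineages.remove(lin)
                events.append({"type": "loss", "time": t,
                               "donor": _edge_name(lin.host), "recipient": None,
                               "cause": "loss"})
            continue
        # deterministic host event(s): speciation or leaf arrival
        t = next_host_t
        for lin in [l for l in lineages if time_of[id(l.host)] == t]:
            lineages.remove(lin)
            pnode = lin.parent_pnode.add(
                Node(length=t - lin.start_time))
            if lin.host.is_leaf:
                pnode.label = lin.host.label
                events.append({"type": "codivergence", "time": t,
                               "donor": lin.host.label, "recipient": None})
            else:
                for c in lin.host.children:
                    lineages.append(_Lineage(pnode, t, c))

    ptree = PhyloTree(proot)
    survivors = {l.label for l in ptree.leaves() if l.label}
    if not survivors:
        raise ValueError("empty scenario: every parasite was lost; retry with a new seed")
    # prune dead internal paths and unifurcations
    for node in list(ptree.postorder()):
        if node.is_leaf and node.label is None and node.parent is not None:
            node.parent.children.remove(node)
    changed = True
    while changed:
        changed = False
        for node in list(ptree.postorder()):
            if not node.is_leaf and not node.children and node.parent is not None:
                node.parent.children.remove(node)
                changed = True
    ptree.suppress_unifurcations()
    if len(ptree.root.children) == 1:
        ptree.root = ptree.root.children[0]
        ptree.root.parent = None
        ptree.root.length = None
    links = [(lab, lab) for lab in sorted(survivors)]
    return CophyloScenario(host.copy(), ptree, links, events)


def _edge_name(node: Node) -> str:
    return node.label or "internal"


# ---------------------------------------------------------------------------
# sequence evolution
# ---------------------------------------------------------------------------

def scale_branch_lengths(tree: PhyloTree, factor: float) -> PhyloTree:
    """Copy of ``tree`` with every branch multiplied by ``factor`` (the clock
    rate converting time units to expected substitutions per site)."""
    t = tree.copy()
    for n in t.postorder():
        if n.length is not None:
            n.length *= factor
    return t


def simulate_alignment(tree: PhyloTree, model: SubstModel, length: int,
                       seed: int | np.random.Generator = 0) -> MultipleAlignment:
    """Evolve ``length`` sites over ``tree`` under ``model``.

    Root states are drawn from the stationary frequencies; each site carries a
    rate class (invariant or discrete-gamma) drawn from the model's class
    weights; states then evolve by the class-specific transition matrices.
    """
    rng = _rng(seed)
    rates, weights = model.category_rates()
    cat = rng.choice(len(rates), p=weights, size=length)
    lam, U, Uinv = model.eigen()

    def pmats(t: float) -> np.ndarray:
        e = np.exp(np.outer(rates, lam) * t)
        P = np.einsum("ij,cj,jk->cik", U, e, Uinv)
        P = np.clip(P, 0.0, None)
        return P / P.sum(axis=2, keepdims=True)

    states: dict[int, np.ndarray] = {
        id(tree.root): rng.choice(4, p=model.freqs, size=length)
    }
    out: list[SequenceRecord] = []
    for node in tree.preorder():
        if node.parent is None:
            parent_states = states[id(node)]
        else:
            P = pmats(node.length)
            ps = states[id(node.parent)]
            rows = P[cat, ps, :]           # (length, 4)
            u = rng.random(length)
            cum = np.cumsum(rows, axis=1)
            child = (u[:, None] > cum).sum(axis=1)
            states[id(node)] = np.minimum(child, 3)
            parent_states = states[id(node)]
        if node.is_leaf:
            out.append(SequenceRecord(
                node.label, "".join(_STATES[s] for s in parent_states)))
    return MultipleAlignment(out)


# ---------------------------------------------------------------------------
# coding sequences and introns
# ---------------------------------------------------------------------------

def random_cds(n_codons: int, seed: int | np.random.Generator = 0,
               code: GeneticCode = TABLE_4) -> SequenceRecord:
    """Random CDS: ATG start, no internal stop under ``code``, no trailing stop."""
    rng = _rng(seed)
    codons = ["ATG"]
    bases = list(_STATES)
    stops = {c for c, aa in code.codon_map.items() if aa == "*"}
    while len(codons) < n_codons:
        c = "".join(bases[i] for i in rng.integers(0, 4, size=3))
        if c not in stops:
            codons.append(c)
    return SequenceRecord("ref_cds", "".join(codons))


def make_intron(length: int, seed: int | np.random.Generator = 0,
                with_orf: bool = True, orf_aa: int = 80) -> str:
    """A synthetic group-I-intron-like insert.

    With ``with_orf`` the intron carries a single homing-endonuclease-style
    ORF: start codon, a body free of table-4 stops containing the LAGLIDADG
    motif and at least one TGA (tryptophan under table 4, stop under the
    standard code), and a TAA terminator.
    """
    rng = _rng(seed)
    bases = list(_STATES)

    def rand_nt(k: int) -> str:
        return "".join(bases[i] for i in rng.integers(0, 4, size=k))

    if not with_orf:
        return rand_nt(length)
    body: list[str] = []
    motif_at = max(1, orf_aa // 3)
    tga_at = motif_at + len(_LAGLIDADG_CODONS) + 2
    i = 0
    while len(body) < orf_aa:
        if i == motif_at:
            body.extend(_LAGLIDADG_CODONS)
            i += len(_LAGLIDADG_CODONS)
            continue
        if i == tga_at:
            body.append("TGA")
            i += 1
            continue
        c = rand_nt(3)
        if c not in _TABLE4_STOPS and c != "TGA":
            body.append(c)
            i += 1
    orf = "ATG" + "".join(body) + "TAA"
    if length < len(orf) + 6:
        raise ValueError(f"intron length {length} too short for a {orf_aa}-aa ORF")
    lead = int(rng.integers(3, length - len(orf) - 2))
    return rand_nt(lead) + orf + rand_nt(length - len(orf) - lead)


def mutate_sequence(seq: str, rate: float,
                    seed: int | np.random.Generator = 0) -> str:
    """Point-substitute a fraction ``rate`` of positions (to a different base)."""
    rng = _rng(seed)
    chars = list(seq.upper())
    hits = np.nonzero(rng.random(len(chars)) < rate)[0]
    for i in hits:
        if chars[i] in _STATES:
            alternatives = [b for b in _STATES if b != chars[i]]
            chars[i] = alternatives[int(rng.integers(3))]
    return "".join(chars)


def inject_intron(cds: SequenceRecord, site: int, intron_seq: str) -> SequenceRecord:
    """Insert ``intron_seq`` immediately after CDS position ``site`` (1-based).

    ``site = len(cds)`` appends at the 3' end.  The result's length is exactly
    ``len(cds) + len(intron_seq)``.
    """
    if not 1 <= site <= len(cds.seq):
        raise ValueError(f"insertion site {site} outside 1..{len(cds.seq)}")
    if not intron_seq:
        raise ValueError("empty intron sequence")
    seq = cds.seq[:site] + intron_seq.upper() + cds.seq[site:]
    return SequenceRecord(cds.id, seq, cds.alphabet)


# ---------------------------------------------------------------------------
# packaged scenarios
# ---------------------------------------------------------------------------

@dataclass
class SimParams:
    """Study conditions for a two-partition host/intron dataset."""

    n_hosts: int = 12
    birth_rate: float = 1.0
    switch_rate: float = 0.0
    loss_rate: float = 0.0
    n_switches: Optional[int] = None
    host_length: int = 630
    intron_length: int = 1078
    host_clock: float = 0.15    # substitutions/site per unit time, cox1 partition
    intron_clock: float = 0.15  # intron partition (raise for a faster parasite)
    model: str = "JC"
    seed: int = 0
    #: horizontal-transfer alternatives only: require that the realised
    #: switches leave topological discordance among the surviving taxa (a
    #: transfer whose trace is erased by subsequent losses is observationally
    #: identical to vertical transmission)
    require_discordance: bool = False


def simulate_dataset(params: SimParams) -> tuple[CophyloScenario,
                                                 MultipleAlignment,
                                                 MultipleAlignment]:
    """Scenario plus host/intron alignments over the intron-bearing taxa."""
    from .phylo_core.tree import PhyloTree as _PT  # avoid cycle at import time
    from .phylo_core import robinson_foulds
    rng = np.random.default_rng(params.seed)
    scen = None
    for _ in range(100):
        host = simulate_host_tree(params.n_hosts, params.birth_rate, rng)
        try:
            cand = simulate_cophylogeny(host, params.switch_rate,
                                        params.loss_rate, rng,
                                        n_switches=params.n_switches)
        except ValueError:
            continue
        if cand.parasite_tree.n_leaves() < 4:
            continue
        if params.require_discordance:
            taxa = {p for _, p in cand.links}
            if robinson_foulds(cand.host_tree.restrict(taxa),
                               cand.parasite_tree) == 0:
                continue
        scen = cand
        break
    if scen is None:
        raise ValueError("could not generate a scenario with >= 4 surviving introns")
    taxa = {p for _, p in scen.links}
    model = SubstModel.from_string(params.model)
    host_sub = scale_branch_lengths(
        scen.host_tree.restrict(taxa), params.host_clock)
    para_sub = scale_branch_lengths(
        scen.parasite_tree, params.intron_clock)
    aln_host = simulate_alignment(host_sub, model, params.host_length, rng)
    aln_intron = simulate_alignment(para_sub, model, params.intron_length, rng)
    return scen, aln_host, aln_intron
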