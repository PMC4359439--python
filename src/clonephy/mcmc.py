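"""Posterior sampling for the clone tree.

The state is a lazily materialized stick-breaking tree (``tssb``) plus an
assignment of every mutation (SSMs and CNV pseudo-SSMs) to a node.  One MCMC
iteration performs, in order:

1. conjugate resampling of the depth/branch sticks given assignment counts;
2. a slice-sampling sweep over mutation assignments: candidates are drawn
   from the stick-breaking prior mass by quantile descent (materializing
   nodes lazily) and accepted against a likelihood slice, shrinking the
   search interval toward the current node's path on rejection;
3. merge proposals relocating all mutations of a node to an adjacent node
   (healing duplicate-phi states left over from cluster formation);
4. a block Metropolis–Hastings update of the per-sample auxiliary masses
   eta, proposing a full simplex vector from an asymmetric Dirichlet
   centred on the current state; multi-sample data use one global
   accept/reject over the product of per-sample posteriors.

The complete-data log likelihood is recorded each iteration; the chain
after burn-in is returned as ``ChainSample`` snapshots.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

from . import vaf_model
from .genome_model import CNV, SSM, InputError, PseudoSSM, UNKNOWN, MATERNAL, PATERNAL, \
    associate_ssms_to_cnvs, cnv_to_pseudo_ssm
from .tssb import TreeNode, TreeState, add_node, prune_empty_nodes, remove_node

__all__ = [
    "MCMCConfig",
    "SMOKE_PROFILE",
    "Dataset",
    "ChainSample",
    "Sampler",
    "run_mcmc",
    "best_tree",
    "loglik_trace",
    "autocorrelation",
    "dataset_log_likelihood",
    "assignment_log_prior",
    "complete_data_log_likelihood",
    "modal_population_count",
    "pruned_population_count",
]


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler settings; defaults follow the reference protocol
    (2,500 iterations, 100 burn-in, 5,000 inner MH steps, Dirichlet scale 100)."""

    n_iterations: int = 2500
    burn_in: int = 100
    mh_iterations: int = 5000
    mh_dirichlet_scale: float = 100.0
    dirichlet_floor: float = 0.01
    seed: int = 0
    alpha: float = 25.0
    gamma: float = 1.0
    lam: float = 0.25
    root_can_hold_mutations: bool = False

    def __post_init__(self) -> None:
        if self.n_iterations <= 0 or self.mh_iterations < 0:
            raise ValueError("iteration counts must be positive")
        if not 0 <= self.burn_in < self.n_iterations:
            raise ValueError("burn_in must satisfy 0 <= burn_in < n_iterations")


#: reduced profile for fast test runs
SMOKE_PROFILE = MCMCConfig(n_iterations=500, burn_in=50, mh_iterations=500)


@dataclass
class Dataset:
    """Inference-ready bundle: SSMs, CNVs, derived pseudo-SSMs and the
    SSM-to-CNV overlap map."""

    ssms: list[SSM]
    cnvs: list[CNV] = field(default_factory=list)
    pseudo_ssms: list[PseudoSSM] = field(default_factory=list)
    overlap: dict[str, list[str]] = field(default_factory=dict)

    @classmethod
    def build(cls, ssms: Sequence[SSM], cnvs: Sequence[CNV] = (),
              support_depth: Optional[int] = None) -> "Dataset":
        """Derive pseudo-SSMs (one per CNV) and the overlap map.

        ``support_depth``, when given, overrides every CNV's own value
        (callers typically pass ``default_support_depth(ssms)``).
        """
        ssms = list(ssms)
        if support_depth is not None:
            cnvs = [replace(c, support_depth=support_depth) for c in cnvs]
        if not ssms and not cnvs:
            raise InputError("empty dataset")
        pseudo = [cnv_to_pseudo_ssm(c) for c in cnvs]
        n_samples = {m.n_samples for m in ssms} | {c.n_samples for c in cnvs}
        if len(n_samples) > 1:
            raise InputError(f"inconsistent sample counts: {sorted(n_samples)}")
        return cls(ssms=ssms, cnvs=list(cnvs), pseudo_ssms=pseudo,
                   overlap=associate_ssms_to_cnvs(ssms, cnvs))

    @property
    def mutations(self) -> list[SSM]:
        return self.ssms + self.pseudo_ssms

    @property
    def n_samples(self) -> int:
        return self.mutations[0].n_samples

    @property
    def cnvs_by_id(self) -> dict[str, CNV]:
        return {c.id: c for c in self.cnvs}

    def pseudo_for_cnv(self, cnv_id: str) -> PseudoSSM:
        for p in self.pseudo_ssms:
            if p.source_cnv_id == cnv_id:
                return p
        raise KeyError(cnv_id)


@dataclass
class ChainSample:
    """One recorded MCMC draw: serializable tree snapshot plus its
    complete-data log likelihood (read-count likelihood plus the log
    stick-breaking mass of every mutation's node)."""

    tree: dict
    log_likelihood: float
    iteration: int


# ---------------------------------------------------------------------------
# Fast likelihood engine
# ---------------------------------------------------------------------------

_CASE_COEFFS = {
    vaf_model.PhyloRelation.NO_SSM_NO_CNV: lambda c, phase: (2.0, 0.0),
    vaf_model.PhyloRelation.NO_SSM_WITH_CNV: lambda c, phase: (float(c.C), 0.0),
    vaf_model.PhyloRelation.SSM_NO_CNV: lambda c, phase: (1.0, 1.0),
    vaf_model.PhyloRelation.CNV_THEN_SSM: lambda c, phase: (float(max(0, c.C - 1)), 1.0),
    vaf_model.PhyloRelation.SSM_THEN_CNV: lambda c, phase: (
        (float(c.Cp), float(c.Cm)) if phase == MATERNAL else (float(c.Cm), float(c.Cp))),
}


def _binom_const(a: np.ndarray, d: np.ndarray) -> np.ndarray:
    return gammaln(d + 1.0) - gammaln(a + 1.0) - gammaln(d - a + 1.0)


class _Engine:
    """Vectorized complete-data log likelihood as a function of eta.

    Captures the tree topology and assignment at construction; mutations
    whose locus is CNV-free depend on eta only through phi of their node,
    while CNV-affected SSMs contribute through per-node Nr/Nv coefficient
    vectors (which depend on topology and assignment, not on eta).
    """

    def __init__(self, tree: TreeState, dataset: Dataset,
                 assignment: Mapping[str, TreeNode]):
        self.nodes = tree.nodes()
        self.K = len(self.nodes)
        self.n_samples = tree.n_samples
        index = {id(u): i for i, u in enumerate(self.nodes)}
        self.parent_idx = np.array(
            [index[id(u.parent)] if u.parent else -1 for u in self.nodes], dtype=np.int64)

        cnvs_by_id = dataset.cnvs_by_id
        simple: list[tuple[SSM, int]] = []
        self.affected: list[dict] = []
        for m in dataset.mutations:
            overlaps = dataset.overlap.get(m.id, [])
            node = assignment[m.id]
            if not overlaps:
                simple.append((m, index[id(node)]))
                continue
            cnv_nodes = {cid: assignment[dataset.pseudo_for_cnv(cid).id] for cid in overlaps}
            crM = np.zeros(self.K)
            cvM = np.zeros(self.K)
            crP = np.zeros(self.K)
            cvP = np.zeros(self.K)
            feasible = True
            for j, u in enumerate(self.nodes):
                rel, gov = vaf_model.classify_relation(tree, node, u, cnv_nodes)
                cnv = cnvs_by_id[gov] if gov is not None else None
                if rel is vaf_model.PhyloRelation.CNV_THEN_SSM and cnv.C < 1:
                    feasible = False  # no surviving copy to mutate
                    break
                crM[j], cvM[j] = _CASE_COEFFS[rel](cnv, MATERNAL)
                crP[j], cvP[j] = _CASE_COEFFS[rel](cnv, PATERNAL)
            if not feasible:
                phases = []
            elif m.phase == PATERNAL:
                phases = [(crP, cvP)]
            elif m.phase == UNKNOWN and (np.any(crM != crP) or np.any(cvM != cvP)):
                phases = [(crM, cvM), (crP, cvP)]
            else:
                phases = [(crM, cvM)]
            self.affected.append({
                "a": m.a.astype(float), "d": m.d.astype(float),
                "const": _binom_const(m.a.astype(float), m.d.astype(float)),
                "eps": m.epsilon, "phases": phases,
            })

        if simple:
            self.simple_z = np.array([z for _, z in simple], dtype=np.int64)
            self.simple_a = np.stack([m.a for m, _ in simple]).astype(float).T  # (S, M)
            self.simple_d = np.stack([m.d for m, _ in simple]).astype(float).T
            self.simple_const = _binom_const(self.simple_a, self.simple_d)
            self.simple_mu_r = np.array([m.mu_r for m, _ in simple])
            self.simple_mu_v = np.array([m.mu_v for m, _ in simple])
        else:
            self.simple_z = None

    def eta_matrix(self) -> np.ndarray:
        return np.stack([u.eta for u in self.nodes]).T.copy()  # (S, K)

    def write_back(self, eta_mat: np.ndarray) -> None:
        for i, u in enumerate(self.nodes):
            u.eta[:] = eta_mat[:, i]

    def phi(self, eta_mat: np.ndarray) -> np.ndarray:
        phi = eta_mat.copy()
        for i in range(self.K - 1, 0, -1):
            phi[:, self.parent_idx[i]] += phi[:, i]
        return phi

    def loglik(self, eta_mat: np.ndarray) -> float:
        phi = self.phi(eta_mat)
        total = 0.0
        if self.simple_z is not None:
            p = ((1.0 - phi[:, self.simple_z]) * self.simple_mu_r
                 + phi[:, self.simple_z] * self.simple_mu_v)
            p = np.clip(p, 1e-300, 1.0 - 1e-16)
            total += float(np.sum(self.simple_const + self.simple_a * np.log(p)
                                  + (self.simple_d - self.simple_a) * np.log1p(-p)))
        for aff in self.affected:
            if not aff["phases"]:
                return -np.inf
            per_phase = []
            for cr, cv in aff["phases"]:
                ll = 0.0
                for s in range(self.n_samples):
                    Nr = float(cr @ eta_mat[s])
                    Nv = float(cv @ eta_mat[s])
                    if Nr + Nv <= 0.0:
                        ll = -np.inf
                        break
                    eps = aff["eps"]
                    zeta = (Nr * (1.0 - eps) + Nv * eps) / (Nr + Nv)
                    zeta = min(max(zeta, 1e-300), 1.0 - 1e-16)
                    ll += float(aff["const"][s] + aff["a"][s] * math.log(zeta)
                                + (aff["d"][s] - aff["a"][s]) * math.log1p(-zeta))
                per_phase.append(ll)
            if len(per_phase) == 1:
                total += per_phase[0]
            else:
                total += float(logsumexp(per_phase) - math.log(len(per_phase)))
        return total


def dataset_log_likelihood(tree: TreeState, dataset: Dataset,
                           assignment: Mapping[str, TreeNode]) -> float:
    """Reference-path data log likelihood: per-mutation evaluation through
    :func:`vaf_model.ssm_log_likelihood` (no vectorization)."""
    eta_maps = [tree.eta_map(s) for s in range(tree.n_samples)]
    total = 0.0
    for m in dataset.mutations:
        overlaps = dataset.overlap.get(m.id, [])
        cnv_nodes = {cid: assignment[dataset.pseudo_for_cnv(cid).id] for cid in overlaps}
        total += vaf_model.ssm_log_likelihood(
            m, tree, assignment[m.id], cnv_nodes, dataset.cnvs_by_id, eta_maps)
    return total


def assignment_log_prior(tree: TreeState, assignment: Mapping[str, TreeNode]) -> float:
    """Sum over mutations of the log stick-breaking mass of their node."""
    weights, _ = tree.node_weights()
    return float(sum(math.log(max(weights[node], 1e-300))
                     for node in assignment.values()))


def complete_data_log_likelihood(tree: TreeState, dataset: Dataset,
                                 assignment: Mapping[str, TreeNode]) -> float:
    """Joint log probability of read counts and assignments given the tree:
    sum_i [log w_{z_i} + log p(a_i | ...)], the quantity used to rank
    sampled trees."""
    return dataset_log_likelihood(tree, dataset, assignment) + \
        assignment_log_prior(tree, assignment)


# ---------------------------------------------------------------------------
# Sampler
# ---------------------------------------------------------------------------

def _subtree_phi(node: TreeNode, sample: int) -> float:
    total = float(node.eta[sample])
    for child in node.children:
        total += _subtree_phi(child, sample)
    return total


def _dirichlet_logpdf(x: np.ndarray, alpha: np.ndarray) -> float:
    return float(np.sum((alpha - 1.0) * np.log(x)) - np.sum(gammaln(alpha))
                 + gammaln(np.sum(alpha)))


class Sampler:
    """MCMC sampler over (topology, assignment, eta)."""

    def __init__(self, dataset: Dataset, config: MCMCConfig):
        if not dataset.mutations:
            raise InputError("empty dataset")
        self.dataset = dataset
        self.config = config
        root_seq = np.random.SeedSequence(config.seed)
        kids = root_seq.spawn(4)
        self.rng_init = np.random.default_rng(kids[0])
        self.rng_assign = np.random.default_rng(kids[1])
        self.rng_eta = np.random.default_rng(kids[2])
        self.rng_sticks = np.random.default_rng(kids[3])

        self.tree = TreeState(n_samples=dataset.n_samples, alpha=config.alpha,
                              gamma=config.gamma, lam=config.lam)
        first = add_node(self.tree, self.tree.root, self.rng_init)
        self.assignment: dict[str, TreeNode] = {}
        for m in dataset.mutations:
            self._attach(m.id, first)

    # -- assignment bookkeeping --------------------------------------------

    def _attach(self, mut_id: str, node: TreeNode) -> None:
        self.assignment[mut_id] = node
        node.mutations.append(mut_id)

    def _detach(self, mut_id: str) -> TreeNode:
        node = self.assignment.pop(mut_id)
        node.mutations.remove(mut_id)
        return node

    def _dependents(self, mutation: SSM) -> list[SSM]:
        """SSMs whose likelihood depends on where ``mutation`` sits (the SSMs
        overlapped by a pseudo-SSM's source CNV)."""
        if not isinstance(mutation, PseudoSSM):
            return []
        cid = mutation.source_cnv_id
        return [s for s in self.dataset.ssms if cid in self.dataset.overlap.get(s.id, [])]

    def _mutation_loglik(self, mutation: SSM, node: TreeNode,
                         eta_maps: list[dict]) -> float:
        overlaps = self.dataset.overlap.get(mutation.id, [])
        cnv_nodes = {cid: self.assignment[self.dataset.pseudo_for_cnv(cid).id]
                     for cid in overlaps}
        try:
            return vaf_model.ssm_log_likelihood(
                mutation, self.tree, node, cnv_nodes, self.dataset.cnvs_by_id, eta_maps)
        except (vaf_model.DegenerateLocusError, vaf_model.ConstraintError):
            return -np.inf

    # -- stick updates ------------------------------------------------------

    def resample_sticks(self) -> None:
        """Conjugate Beta updates of nu and psi given assignment counts."""
        counts: dict[int, int] = {}
        subtree: dict[int, int] = {}

        def descend(u: TreeNode) -> int:
            n = len(u.mutations)
            counts[id(u)] = n
            total = n + sum(descend(c) for c in u.children)
            subtree[id(u)] = total
            return total

        descend(self.tree.root)
        for u in self.tree.nodes():
            below = subtree[id(u)] - counts[id(u)]
            u.nu = float(self.rng_sticks.beta(
                1.0 + counts[id(u)],
                max(self.tree.alpha * self.tree.lam ** u.depth, 1e-6) + below))
            later = 0
            for child in reversed(u.children):
                child.psi = float(self.rng_sticks.beta(
                    1.0 + subtree[id(child)], self.tree.gamma + later))
                later += subtree[id(child)]

    # -- assignment sweep ---------------------------------------------------

    def _mutation_loglik_at(self, mutation, node: TreeNode, deps) -> float:
        """Log likelihood of placing ``mutation`` at ``node`` given the rest
        of the current state, including the terms of mutations whose VAF
        depends on this placement (SSMs overlapped by a pseudo-SSM's CNV)."""
        eta_maps = [self.tree.eta_map(s) for s in range(self.tree.n_samples)]
        if not deps and not self.dataset.overlap.get(mutation.id):
            ll = 0.0
            for s in range(self.tree.n_samples):
                phi = _subtree_phi(node, s)
                p = (1.0 - phi) * mutation.mu_r + phi * mutation.mu_v
                ll += float(vaf_model.binom_logpmf(mutation.a[s], mutation.d[s], p))
            return ll
        prev = self.assignment.get(mutation.id)
        self.assignment[mutation.id] = node
        ll = self._mutation_loglik(mutation, node, eta_maps)
        for dep in deps:
            ll += self._mutation_loglik(dep, self.assignment[dep.id], eta_maps)
        if prev is None:
            del self.assignment[mutation.id]
        else:
            self.assignment[mutation.id] = prev
        return ll

    def _find_node(self, u: float) -> TreeNode:
        """Quantile descent through the stick-breaking measure: return the
        node whose prior-mass interval contains ``u``, materializing sticks
        and nodes lazily where ``u`` falls into unallocated mass."""
        rng = self.rng_assign
        node = self.tree.root
        while True:
            if node.depth >= 15 or u < node.nu:
                return node
            u = (u - node.nu) / max(1.0 - node.nu, 1e-300)
            # walk the child sticks; extend with fresh sticks as needed
            while True:
                for child in node.children:
                    if u < child.psi:
                        node = child
                        break
                    u = (u - child.psi) / max(1.0 - child.psi, 1e-300)
                else:
                    child = self.tree._new_node(node)
                    child.nu = float(rng.beta(
                        1.0, max(self.tree.alpha * self.tree.lam ** child.depth, 1e-6)))
                    child.psi = float(rng.beta(1.0, self.tree.gamma))
                    for s in range(self.tree.n_samples):
                        draw = float(rng.uniform(0.0, node.eta[s])) if node.eta[s] > 0 else 0.0
                        child.eta[s] = draw
                        node.eta[s] -= draw
                    node.children.append(child)
                    continue
                break

    def resample_assignments(self) -> None:
        """Slice-sampled reassignment of every mutation over the lazily
        materialized stick-breaking tree.

        For each mutation a slice level is drawn under its current
        log likelihood; candidate nodes are repeatedly drawn from the prior
        mass via quantile descent (materializing new nodes where the draw
        lands in unallocated mass) and the first candidate above the slice
        is accepted, shrinking the search interval toward the current node's
        path after each rejection.
        """
        rng = self.rng_assign
        barred_root = not self.config.root_can_hold_mutations
        for mutation in self.dataset.mutations:
            current = self.assignment[mutation.id]
            deps = self._dependents(mutation)
            cur_ll = self._mutation_loglik_at(mutation, current, deps)
            if math.isfinite(cur_ll):
                slice_ll = math.log(rng.uniform(1e-300, 1.0)) + cur_ll
            else:
                slice_ll = -math.inf
            cur_path = self.tree.node_path(current)
            min_u, max_u = 0.0, 1.0
            for _ in range(100):
                u = rng.uniform(min_u, max_u)
                cand = self._find_node(u)
                cand_path = self.tree.node_path(cand)
                if not (barred_root and cand is self.tree.root):
                    ll = self._mutation_loglik_at(mutation, cand, deps)
                    if ll > slice_ll:
                        if cand is not current:
                            self._detach(mutation.id)
                            self._attach(mutation.id, cand)
                        break
                if max_u - min_u < 1e-12:
                    break
                if cand_path < cur_path:
                    min_u = u
                else:
                    max_u = u
        self._cull_empty_leaves()

    def _cull_empty_leaves(self) -> None:
        """Lazy-tree canonicalization: drop mutation-free leaves and splice
        mutation-free internal nodes into their parent (children reattached
        in place, eta folded upward).  Both moves conserve eta exactly and
        leave every mutation's likelihood unchanged — an empty node's
        five-case classification always coincides with its parent's."""
        changed = True
        while changed:
            changed = False
            for u in self.tree.nodes():
                if u.parent is None or u.mutations:
                    continue
                if not u.children:
                    remove_node(self.tree, u)
                    changed = True
                else:
                    parent = u.parent
                    slot = parent.children.index(u)
                    parent.eta += u.eta
                    for child in u.children:
                        child.parent = parent
                    parent.children[slot:slot + 1] = u.children
                    u.children = []
                    u.parent = None
                    changed = True

    # -- merge moves --------------------------------------------------------

    def merge_moves(self) -> None:
        """Metropolis proposals collapsing a whole node into an adjacent one.

        Cluster formation can leave two nodes straddling one true population
        (near-duplicate phi); single-mutation moves then have no gradient to
        empty either, so each mutation-bearing node proposes, once per
        iteration, relocating all its mutations to its parent, a sibling or
        a child, together with a Uniform(0, eta_v) share of its cell mass.
        The proposal is accepted on the complete-data posterior ratio (read
        counts plus assignment stick mass) at the proposed eta.  Only the
        forward (merge) direction is proposed; duplicate-split states are
        deliberately suppressed.
        """
        rng = self.rng_assign
        root = self.tree.root
        candidates = [v for v in self.tree.nodes() if v.mutations and v.parent is not None]
        for v in candidates:
            if not v.mutations or v.parent is None:
                continue
            targets = [u for u in [v.parent] + v.parent.children + v.children
                       if u is not v and (u is not root or self.config.root_can_hold_mutations)]
            if not targets:
                continue
            w = targets[int(rng.integers(len(targets)))]
            weights, _ = self.tree.node_weights()
            log_w_term = len(v.mutations) * (
                math.log(max(weights[w], 1e-300)) - math.log(max(weights[v], 1e-300)))

            engine = _Engine(self.tree, self.dataset, self.assignment)
            ll_before = engine.loglik(engine.eta_matrix())

            saved_v_eta = v.eta.copy()
            saved_w_eta = w.eta.copy()
            moved = list(v.mutations)
            if w is not v.parent:
                transfer = np.array([rng.uniform(0.0, v.eta[s])
                                     for s in range(self.tree.n_samples)])
                w.eta += transfer
                v.eta -= transfer
            for mid in moved:
                self._detach(mid)
                self._attach(mid, w)

            engine2 = _Engine(self.tree, self.dataset, self.assignment)
            ll_after = engine2.loglik(engine2.eta_matrix())
            log_accept = ll_after - ll_before + log_w_term
            if not (log_accept >= 0
                    or (math.isfinite(log_accept)
                        and rng.uniform() < math.exp(log_accept))):
                for mid in moved:
                    self._detach(mid)
                    self._attach(mid, v)
                v.eta[:] = saved_v_eta
                w.eta[:] = saved_w_eta
        self._cull_empty_leaves()

    # -- eta Metropolis-Hastings -------------------------------------------

    def mh_update_eta(self) -> float:
        """Block MH over the per-sample eta simplex vectors.

        Proposals are Dirichlet(scale * eta + floor) per sample; a single
        global accept/reject uses the product of per-sample likelihoods plus
        the asymmetric-proposal correction.  Returns the acceptance rate.
        """
        cfg = self.config
        engine = _Engine(self.tree, self.dataset, self.assignment)
        eta = engine.eta_matrix()
        eta = np.clip(eta, 1e-10, None)
        eta /= eta.sum(axis=1, keepdims=True)
        cur_ll = engine.loglik(eta)
        accepted = 0
        scale, floor = cfg.mh_dirichlet_scale, cfg.dirichlet_floor
        rng = self.rng_eta
        for _ in range(cfg.mh_iterations):
            prop = np.empty_like(eta)
            log_q = 0.0
            for s in range(engine.n_samples):
                conc = scale * eta[s] + floor
                y = rng.dirichlet(conc)
                y = np.clip(y, 1e-10, None)
                y /= y.sum()
                prop[s] = y
                log_q -= _dirichlet_logpdf(y, conc)
            for s in range(engine.n_samples):
                log_q += _dirichlet_logpdf(eta[s], scale * prop[s] + floor)
            prop_ll = engine.loglik(prop)
            if not math.isfinite(prop_ll):
                continue
            log_accept = prop_ll - cur_ll + log_q if math.isfinite(cur_ll) else math.inf
            if log_accept >= 0 or rng.uniform() < math.exp(max(log_accept, -700.0)):
                eta = prop
                cur_ll = prop_ll
                accepted += 1
        engine.write_back(eta)
        self._last_loglik = cur_ll
        return accepted / max(cfg.mh_iterations, 1)

    # -- main loop ----------------------------------------------------------

    def step(self) -> float:
        self.resample_sticks()
        self.resample_assignments()
        self.merge_moves()
        self.mh_update_eta()
        self._last_complete = self._last_loglik + assignment_log_prior(
            self.tree, self.assignment)
        return self._last_complete

    def snapshot(self, iteration: int) -> ChainSample:
        """Record the complete-data log likelihood (data + assignment mass)."""
        return ChainSample(tree=self.tree.to_dict(),
                           log_likelihood=self._last_complete,
                           iteration=iteration)


def run_mcmc(dataset: Dataset, config: MCMCConfig) -> list[ChainSample]:
    """Run the full sampler; returns post-burn-in samples in order.

    Deterministic given ``config.seed``: all subsystem generators are spawned
    from one root seed sequence.
    """
    sampler = Sampler(dataset, config)
    chain: list[ChainSample] = []
    for it in range(config.n_iterations):
        sampler.step()
        if it >= config.burn_in:
            chain.append(sampler.snapshot(it))
    return chain


def best_tree(chain: Sequence[ChainSample]) -> ChainSample:
    """Sample with the highest complete-data log likelihood (earliest wins ties)."""
    if not chain:
        raise ValueError("empty chain")
    best = chain[0]
    for sample in chain[1:]:
        if sample.log_likelihood > best.log_likelihood:
            best = sample
    return best


def loglik_trace(chain: Sequence[ChainSample]) -> np.ndarray:
    return np.array([s.log_likelihood for s in chain])


def autocorrelation(trace: np.ndarray, max_lag: int = 50) -> np.ndarray:
    """Normalized autocorrelation function of a scalar trace."""
    x = np.asarray(trace, dtype=float) - np.mean(trace)
    var = np.dot(x, x)
    if var == 0:
        return np.ones(min(max_lag, len(x) - 1) + 1)
    n_lags = min(max_lag, len(x) - 1)
    return np.array([np.dot(x[: len(x) - k], x[k:]) / var for k in range(n_lags + 1)])


def modal_population_count(chain: Sequence[ChainSample]) -> int:
    """Most frequent pruned population count across the chain (ties -> smaller)."""
    counts: dict[int, int] = {}
    for sample in chain:
        k = pruned_population_count(sample)
        counts[k] = counts.get(k, 0) + 1
    return min(sorted(counts), key=lambda k: (-counts[k], k))


def pruned_population_count(sample: ChainSample) -> int:
    """Number of populations after stripping mutation-free leaves (the
    mutation-free normal root is always counted)."""
    tree = TreeState.from_dict(sample.tree)
    return len(prune_empty_nodes(tree).nodes())
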