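"""Marginal ancestral sequence reconstruction on a fixed rooted phylogeny.

The likelihood machinery is Felsenstein's pruning algorithm under a
reversible empirical amino-acid model with discrete-gamma rate categories.
Marginal posteriors at an internal node are obtained by an inside-outside
pass: the "inside" (downward) conditional likelihood of the subtree below
the node is combined with the "outside" (upward) likelihood of the rest of
the tree, per rate category, and categories are weighted by their share of
the site likelihood.  A rerooting implementation of the same quantity is
provided as an independent cross-check (for a reversible model the marginal
posterior at a node equals the root posterior after rerooting there).

Gaps and unknown residues are missing data in the likelihood (all-ones
conditional vectors); the ancestral presence/absence of each column is
decided separately by Fitch parsimony on the gap pattern, mirroring the
two-track treatment (probabilistic states, parsimony length) standard in
ancestral protein resurrection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .evomodel import AA_INDEX, AMINO_ACIDS, N_STATES, SubstitutionModel, encode_alignment
from .formats import GAP, Alignment, PhyloTree, TreeError, TreeNode

logger = logging.getLogger(__name__)

AMBIGUITY_PP = 0.2  # second-best state above this flags a site as ambiguous
_TIE_TOL = 1e-12


class ASRError(ValueError):
    pass


@dataclass
class AncestralProfile:
    """Per-site marginal posteriors at one internal node.

    ``posterior`` has one row per alignment column (all columns, including
    those later masked absent); rows sum to 1.  ``map_state``/``alt_state``
    are one-letter codes, ``pp_map``/``pp_alt`` their posterior
    probabilities, and ``ambiguous`` flags sites whose second-best state has
    posterior probability above the ambiguity threshold.
    """

    node: str
    posterior: np.ndarray  # (n_sites, 20)
    map_state: np.ndarray  # (n_sites,) '<U1'
    pp_map: np.ndarray
    alt_state: np.ndarray
    pp_alt: np.ndarray
    ambiguous: np.ndarray  # bool

    @property
    def n_sites(self) -> int:
        return self.posterior.shape[0]


@dataclass
class GapMask:
    """Fitch-parsimony presence/absence calls for one node, per column."""

    node: str
    present: np.ndarray  # (n_sites,) bool
    state_sets: list[frozenset]  # diagnostic: bottom-up Fitch sets at the node

    @property
    def n_present(self) -> int:
        return int(self.present.sum())


# ---------------------------------------------------------------------------
# Pruning engine


class _Pruning:
    """Shared state for likelihood computations on one (alignment, tree,
    model) triple.  Conditional likelihoods are scaled per node and site;
    scale factors accumulate in log space."""

    def __init__(self, alignment: Alignment, tree: PhyloTree, model: SubstitutionModel):
        leaf_set = set(tree.leaf_labels())
        if leaf_set != set(alignment.ids):
            missing = sorted(leaf_set - set(alignment.ids))
            extra = sorted(set(alignment.ids) - leaf_set)
            raise ASRError(
                f"leaf labels do not match alignment ids "
                f"(tree-only: {missing}, alignment-only: {extra})"
            )
        self.alignment = alignment
        self.tree = tree
        self.model = model
        self.encoded = encode_alignment(alignment)
        self.row_of = {sid: i for i, sid in enumerate(alignment.ids)}
        self.S = alignment.n_sites

    def _leaf_partial(self, node: TreeNode) -> np.ndarray:
        codes = self.encoded[self.row_of[node.label]]
        L = np.zeros((self.S, N_STATES))
        observed = codes < N_STATES
        L[observed, codes[observed]] = 1.0
        L[~observed, :] = 1.0  # gap / X: missing data
        return L

    def down_pass(self, rate: float):
        """Inside (subtree) conditional likelihoods for one rate category.

        Returns dicts node -> (S,20) scaled partials and node -> (S,) log
        scale factors.
        """
        down, logscale = {}, {}
        for node in self.tree.postorder():
            if node.is_leaf:
                down[node] = self._leaf_partial(node)
                logscale[node] = np.zeros(self.S)
            else:
                L = np.ones((self.S, N_STATES))
                ls = np.zeros(self.S)
                for child in node.children:
                    P = self.model.transition_matrix(child.length, rate)
                    L = L * (down[child] @ P.T)
                    ls = ls + logscale[child]
                m = L.max(axis=1)
                m[m == 0.0] = 1.0
                down[node] = L / m[:, None]
                logscale[node] = ls + np.log(m)
        return down, logscale

    def up_pass(self, rate: float, down, logscale_down):
        """Outside likelihoods: Up_v(x) is the likelihood of all data outside
        the subtree of v, jointly with state x at v (root prior included)."""
        up = {self.tree.root: np.tile(self.model.pi, (self.S, 1))}
        logscale_up = {self.tree.root: np.zeros(self.S)}
        for node in self.tree.preorder():
            for child in node.children:
                sib = np.ones((self.S, N_STATES))
                ls_sib = np.zeros(self.S)
                for other in node.children:
                    if other is child:
                        continue
                    P = self.model.transition_matrix(other.length, rate)
                    sib = sib * (down[other] @ P.T)
                    ls_sib = ls_sib + logscale_down[other]
                Pc = self.model.transition_matrix(child.length, rate)
                U = (up[node] * sib) @ Pc
                m = U.max(axis=1)
                m[m == 0.0] = 1.0
                up[child] = U / m[:, None]
                logscale_up[child] = logscale_up[node] + ls_sib + np.log(m)
        return up, logscale_up

    def site_logliks(self) -> np.ndarray:
        """Per-site log-likelihoods, gamma mixture included."""
        per_cat = np.empty((self.model.K, self.S))
        for k, r in enumerate(self.model.rates):
            down, ls = self.down_pass(r)
            root = self.tree.root
            lik = down[root] @ self.model.pi
            per_cat[k] = np.log(lik) + ls[root]
        return logsumexp(per_cat, axis=0) - np.log(self.model.K)

    def node_posteriors(self, node: TreeNode) -> np.ndarray:
        """Marginal posterior over states at ``node`` for every site."""
        K, S = self.model.K, self.S
        post_cat = np.empty((K, S, N_STATES))
        loglik_cat = np.empty((K, S))
        for k, r in enumerate(self.model.rates):
            down, ls_down = self.down_pass(r)
            up, ls_up = self.up_pass(r, down, ls_down)
            joint = down[node] * up[node]  # (S,20), scaled
            total = joint.sum(axis=1)
            loglik_cat[k] = np.log(total) + ls_down[node] + ls_up[node]
            post_cat[k] = joint / total[:, None]
        logw = loglik_cat - logsumexp(loglik_cat, axis=0)  # equal priors 1/K
        return np.einsum("ks,ksx->sx", np.exp(logw), post_cat)


def site_log_likelihood(
    alignment: Alignment, tree: PhyloTree, model: SubstitutionModel, site: int
) -> float:
    """Log-likelihood of one alignment column (1-based)."""
    if not 1 <= site <= alignment.n_sites:
        raise ASRError(f"site {site} outside 1..{alignment.n_sites}")
    return float(_Pruning(alignment, tree, model).site_logliks()[site - 1])


def log_likelihood(
    alignment: Alignment, tree: PhyloTree, model: SubstitutionModel
) -> float:
    """Total log-likelihood of the alignment."""
    return float(_Pruning(alignment, tree, model).site_logliks().sum())


def _profile_from_posterior(node_label: str, post: np.ndarray) -> AncestralProfile:
    order = np.argsort(post, axis=1)
    map_idx = order[:, -1]
    alt_idx = order[:, -2]
    aa = np.array(list(AMINO_ACIDS))
    # alphabetical tie-break on the MAP state (one-letter code order)
    pp_map = np.take_along_axis(post, map_idx[:, None], axis=1)[:, 0]
    for s in range(post.shape[0]):
        tied = np.flatnonzero(post[s] >= pp_map[s] - _TIE_TOL)
        if len(tied) > 1:
            codes = sorted(aa[tied])
            logger.warning(
                "MAP tie at column %d between %s; choosing %s",
                s + 1, "/".join(codes), codes[0],
            )
            map_idx[s] = AA_INDEX[codes[0]]
            rest = [i for i in tied if i != map_idx[s]]
            alt_idx[s] = min(rest, key=lambda i: aa[i])
    pp_map = np.take_along_axis(post, map_idx[:, None], axis=1)[:, 0]
    pp_alt = np.take_along_axis(post, alt_idx[:, None], axis=1)[:, 0]
    return AncestralProfile(
        node=node_label,
        posterior=post,
        map_state=aa[map_idx],
        pp_map=pp_map,
        alt_state=aa[alt_idx],
        pp_alt=pp_alt,
        ambiguous=pp_alt > AMBIGUITY_PP,
    )


def marginal_posteriors(
    alignment: Alignment, tree: PhyloTree, model: SubstitutionModel, node: str
) -> AncestralProfile:
    """Marginal ancestral reconstruction at a labeled internal node."""
    target = tree.find(node)
    if target.is_leaf:
        raise ASRError(f"node {node!r} is a leaf; reconstruction targets internal nodes")
    post = _Pruning(alignment, tree, model).node_posteriors(target)
    return _profile_from_posterior(node, post)


# ---------------------------------------------------------------------------
# Rerooting oracle


def reroot_at(tree: PhyloTree, node_label: str) -> PhyloTree:
    """Return a copy of the tree rerooted at the named internal node.

    Edges on the path to the old root are reversed; if the old root is left
    with a single child its two incident edge lengths are merged.  Under a
    reversible model the likelihood is invariant to this operation.
    """
    tree = tree.copy()
    target = tree.find(node_label)
    if target.is_leaf:
        raise TreeError(f"cannot reroot at leaf {node_label!r}")
    # Collect path target -> old root, then reverse parent/child pointers.
    path = []
    n = target
    while n is not None:
        path.append(n)
        n = n.parent
    orig_lengths = [n.length for n in path]
    for (child, parent), edge_len in zip(zip(path, path[1:]), orig_lengths):
        parent.children.remove(child)
        child.add_child(parent)
        parent.length = edge_len
    target.length = None
    target.parent = None
    old_root = path[-1]
    if len(old_root.children) == 1 and old_root.parent is not None:
        # suppress the degree-2 old root, merging edge lengths
        only = old_root.children[0]
        only.length = (only.length or 0.0) + (old_root.length or 0.0)
        grand = old_root.parent
        grand.children[grand.children.index(old_root)] = only
        only.parent = grand
    return PhyloTree(target)


def marginal_posteriors_by_rerooting(
    alignment: Alignment, tree: PhyloTree, model: SubstitutionModel, node: str
) -> AncestralProfile:
    """Independent route to the marginal posterior: reroot at the node and
    read the root posterior.  Used as a cross-check of the inside-outside
    implementation."""
    rerooted = reroot_at(tree, node)
    post = _Pruning(alignment, rerooted, model).node_posteriors(rerooted.root)
    return _profile_from_posterior(node, post)


# ---------------------------------------------------------------------------
# Fitch parsimony on gap presence/absence

PRESENT = "present"
ABSENT = "absent"


def fitch_gap_mask(
    alignment: Alignment, tree: PhyloTree, node: str, tie: str = PRESENT
) -> GapMask:
    """Presence/absence call for every alignment column at a target node.

    Each column is encoded as a binary character at the leaves (gap = absent;
    residues and 'X' = present).  A bottom-up Fitch pass (intersection where
    non-empty, otherwise union) is followed by top-down refinement from the
    root; remaining two-state ties at the target resolve to ``tie``
    (default "present", favouring a consistent ancestor length).
    """
    if tie not in (PRESENT, ABSENT):
        raise ASRError(f"tie rule must be 'present' or 'absent', got {tie!r}")
    target = tree.find(node)
    if target.is_leaf:
        raise ASRError(f"node {node!r} is a leaf")
    row_of = {sid: i for i, sid in enumerate(alignment.ids)}
    present_leaf = alignment.matrix != GAP  # X counts as presence
    S = alignment.n_sites

    sets: dict[TreeNode, list[frozenset]] = {}
    for n in tree.postorder():
        if n.is_leaf:
            sets[n] = [
                frozenset({PRESENT if present_leaf[row_of[n.label], s] else ABSENT})
                for s in range(S)
            ]
        else:
            child_sets = [sets[c] for c in n.children]
            merged = []
            for s in range(S):
                inter = frozenset.intersection(*(cs[s] for cs in child_sets))
                if inter:
                    merged.append(inter)
                else:
                    merged.append(frozenset.union(*(cs[s] for cs in child_sets)))
            sets[n] = merged

    final: dict[TreeNode, list[str]] = {}
    for n in tree.preorder():
        if n is tree.root:
            final[n] = [
                next(iter(ss)) if len(ss) == 1 else tie for ss in sets[n]
            ]
        else:
            parent_final = final[n.parent]
            final[n] = [
                parent_final[s] if parent_final[s] in sets[n][s]
                else (next(iter(sets[n][s])) if len(sets[n][s]) == 1 else tie)
                for s in range(S)
            ]

    calls = np.array([st == PRESENT for st in final[target]], dtype=bool)
    n_ties = sum(1 for ss in sets[target] if len(ss) > 1)
    if n_ties:
        logger.info(
            "Fitch gap reconstruction at %s: %d tied columns resolved to %s",
            node, n_ties, tie,
        )
    return GapMask(node=node, present=calls, state_sets=sets[target])


# ---------------------------------------------------------------------------
# Sequence construction


def _check_same_node(profile: AncestralProfile, gap_mask: GapMask) -> None:
    if profile.n_sites != len(gap_mask.present):
        raise ASRError(
            f"profile has {profile.n_sites} sites but mask has "
            f"{len(gap_mask.present)}"
        )
    if profile.node != gap_mask.node:
        raise ASRError(
            f"profile is for node {profile.node!r} but mask for {gap_mask.node!r}"
        )


def map_sequence(profile: AncestralProfile, gap_mask: GapMask) -> str:
    """Maximum a posteriori ancestor: MAP states over columns called present."""
    _check_same_node(profile, gap_mask)
    if not gap_mask.present.any():
        logger.warning("all columns absent at %s; empty ancestor", profile.node)
    return "".join(profile.map_state[gap_mask.present])


def altall_sequence(
    profile: AncestralProfile, gap_mask: GapMask, threshold: float = AMBIGUITY_PP
) -> str:
    """Alternative ancestor: the second-best state wherever its posterior
    exceeds the ambiguity threshold, the MAP state elsewhere.  Never
    introduces a gap."""
    _check_same_node(profile, gap_mask)
    take_alt = profile.pp_alt > threshold
    states = np.where(take_alt, profile.alt_state, profile.map_state)
    return "".join(states[gap_mask.present])


def mean_pp(profile: AncestralProfile, gap_mask: GapMask) -> float:
    """Mean posterior probability of the MAP state over present sites."""
    _check_same_node(profile, gap_mask)
    if not gap_mask.present.any():
        raise ASRError(f"no present sites at {profile.node}")
    return float(profile.pp_map[gap_mask.present].mean())
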