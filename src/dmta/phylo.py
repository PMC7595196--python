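"""Phylogenetic diet evolution: time calibration, signal, ancestral states.

Fossil cladograms (topologies in Newick) are time-calibrated from first/last
appearance dates with the "equal" branch-scaling rule, pruned to the taxa
with microwear data, and used to (i) test for phylogenetic signal in PC
scores with Blomberg's K and Pagel's λ, (ii) reconstruct ancestral dietary
positions as continuous characters under Brownian motion, and (iii) draw
the phylogeny through the texture-dietary space (a phylomorphospace).

All covariance math runs on the Brownian-motion variance–covariance matrix
of the tree (shared root-to-MRCA path lengths, in Myr), so polytomies are
handled as genuine multifurcations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import solve_triangular
from scipy.optimize import minimize_scalar

from .guilds import Specimen

__all__ = [
    "StratRange", "TimeTree", "PhyloSignalResult", "TraitReconstruction",
    "TreeParseError", "read_tree", "write_tree", "time_calibrate_equal",
    "prune_tree", "graft_taxon", "select_largest_per_taxon", "tree_vcv",
    "blomberg_k", "pagel_lambda", "ancestral_states", "phylo_texture_space",
    "correlate_scores_with_age",
]

_AGE_TOL = 1e-9


class TreeParseError(ValueError):
    pass


@dataclass(frozen=True)
class StratRange:
    """First (FAD) and last (LAD) appearance ages of a taxon, in Ma."""

    taxon: str
    fad: float
    lad: float

    def __post_init__(self):
        if not (self.fad >= self.lad >= 0):
            raise ValueError(f"{self.taxon}: need FAD >= LAD >= 0, "
                             f"got FAD={self.fad}, LAD={self.lad}")


@dataclass
class TimeTree:
    """A rooted, time-calibrated phylogeny.

    ``tree`` is a dendropy tree whose edge lengths are durations in Myr and
    whose nodes carry an ``age`` attribute in Ma; ``root_age`` is the age of
    the root.  All branch lengths are strictly positive after equal-method
    scaling; every tip sits at its first appearance age.
    """

    tree: dendropy.Tree
    root_age: float

    def tip_labels(self) -> list:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def tip_ages(self) -> dict:
        return {lf.taxon.label: lf.age for lf in self.tree.leaf_node_iter()}

    def validate(self) -> None:
        for nd in self.tree.preorder_node_iter():
            if nd.parent_node is not None:
                if not nd.edge.length > 0:
                    raise ValueError("non-positive branch length after calibration")
                if not nd.parent_node.age > nd.age - _AGE_TOL:
                    raise ValueError("parent age must exceed child age")


@dataclass(frozen=True)
class PhyloSignalResult:
    """A phylogenetic-signal statistic with its significance test."""

    statistic: str                 # "K" or "lambda"
    estimate: float
    p: float | None
    detail: dict = field(default_factory=dict)


@dataclass(frozen=True)
class TraitReconstruction:
    """Ancestral estimates of a continuous trait under Brownian motion.

    ``nodes``: DataFrame indexed by node key ('|'-joined sorted descendant
    tip labels, immune to index drift) with estimate, variance, ci_low,
    ci_high, age.  ``tips``: the observed tip values.  ``sigma2``: ML
    Brownian rate.
    """

    nodes: pd.DataFrame
    tips: pd.Series
    sigma2: float
    root_key: str

    @property
    def root_estimate(self) -> float:
        return float(self.nodes.loc[self.root_key, "estimate"])

    def edge_values(self, tree: "TimeTree", n_points: int = 11):
        """Linearly interpolated values along every edge (for colour-mapped
        plotting of the reconstruction)."""
        est = dict(zip(self.nodes.index, self.nodes["estimate"]))
        out = []
        for nd in tree.tree.preorder_node_iter():
            if nd.parent_node is None:
                continue
            pkey = _node_key(nd.parent_node)
            ckey = _node_key(nd)
            v0 = est[pkey]
            v1 = est[ckey] if ckey in est else float(self.tips[ckey])
            ts = np.linspace(0.0, 1.0, n_points)
            out.append({"parent": pkey, "child": ckey,
                        "t": ts, "value": v0 + (v1 - v0) * ts})
        return out


# ---------------------------------------------------------------------------
# Newick I/O and topology surgery
# ---------------------------------------------------------------------------

def read_tree(newick: str) -> dendropy.Tree:
    """Parse a rooted Newick string; tip labels must be unique."""
    try:
        tree = dendropy.Tree.get(data=newick, schema="newick",
                                 suppress_internal_node_taxa=True)
    except Exception as exc:  # dendropy raises several error types
        raise TreeParseError(f"newick parse error: {exc}") from None
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    dupes = {l for l in labels if labels.count(l) > 1}
    if dupes:
        raise TreeParseError(f"duplicate tip label(s): {', '.join(sorted(dupes))}")
    tree.is_rooted = True
    return tree


def write_tree(tree) -> str:
    """Serialise a (time) tree back to Newick with branch lengths."""
    t = tree.tree if isinstance(tree, TimeTree) else tree
    return t.as_string(schema="newick", suppress_rooting=True).strip()


def _find_tip(tree: dendropy.Tree, label: str):
    for lf in tree.leaf_node_iter():
        if lf.taxon.label == label:
            return lf
    return None


def _find_mrca(tree: dendropy.Tree, labels: Sequence[str]):
    taxa = [t for t in tree.taxon_namespace if t.label in set(labels)]
    if len(taxa) != len(set(labels)):
        missing = set(labels) - {t.label for t in taxa}
        raise ValueError(f"clade taxa not in tree: {', '.join(sorted(missing))}")
    return tree.mrca(taxa=taxa)


def graft_taxon(tree: dendropy.Tree, new_taxon: str, attach_to,
                attach_type: str = "sister_taxon") -> dendropy.Tree:
    """Add ``new_taxon`` as sister to an existing tip or clade.

    Done on the undated topology, before time calibration.  ``attach_to``
    is a tip label (``attach_type="sister_taxon"``) or a sequence of tip
    labels whose MRCA defines the clade (``attach_type="clade"``).
    """
    tree = tree.clone(depth=1)
    if attach_type == "sister_taxon":
        node = _find_tip(tree, attach_to)
        if node is None:
            raise ValueError(f"attachment taxon {attach_to!r} not in tree")
    elif attach_type == "clade":
        node = _find_mrca(tree, list(attach_to))
        if node.is_leaf():
            raise ValueError("clade specification resolves to a single tip; "
                             "use attach_type='sister_taxon'")
    else:
        raise ValueError("attach_type must be 'sister_taxon' or 'clade'")
    parent = node.parent_node
    new_internal = dendropy.Node()
    new_tip = dendropy.Node()
    taxon = tree.taxon_namespace.require_taxon(label=new_taxon)
    new_tip.taxon = taxon
    if parent is None:  # attaching sister to the whole tree: new root
        new_internal.add_child(node)
        new_internal.add_child(new_tip)
        tree.seed_node = new_internal
    else:
        parent.remove_child(node)
        new_internal.add_child(node)
        new_internal.add_child(new_tip)
        parent.add_child(new_internal)
    return tree


def prune_tree(tree, keep: Sequence[str]):
    """Restrict a tree to ``keep`` tips, preserving patristic distances.

    Unary nodes left by the removal are suppressed with their branch
    lengths summed, so pairwise path lengths among kept tips are unchanged.
    Accepts and returns a :class:`TimeTree` (ages preserved) or a bare
    topology.
    """
    keep = list(keep)
    if len(keep) < 2:
        raise ValueError("keep set must contain at least 2 taxa")
    is_time = isinstance(tree, TimeTree)
    t = (tree.tree if is_time else tree).clone(depth=1)
    tips = {lf.taxon.label for lf in t.leaf_node_iter()}
    unknown = set(keep) - tips
    if unknown:
        raise ValueError(f"keep includes taxa not in tree: {', '.join(sorted(unknown))}")
    taxa = [tx for tx in t.taxon_namespace if tx.label in set(keep)]
    t.retain_taxa(taxa)
    t.purge_taxon_namespace()
    if not is_time:
        return t
    # recompute ages from preserved tip ages + summed branch lengths
    tip_age = tree.tip_ages()
    for nd in t.postorder_node_iter():
        if nd.is_leaf():
            nd.age = tip_age[nd.taxon.label]
        else:
            child = nd.child_nodes()[0]
            nd.age = child.age + child.edge.length
    out = TimeTree(tree=t, root_age=t.seed_node.age)
    out.validate()
    return out


# ---------------------------------------------------------------------------
# Time calibration ("equal" method)
# ---------------------------------------------------------------------------

def _as_range_map(ranges) -> dict:
    if isinstance(ranges, Mapping):
        return {k: (v if isinstance(v, StratRange) else StratRange(k, *v))
                for k, v in ranges.items()}
    if isinstance(ranges, pd.DataFrame):
        return {row["taxon"]: StratRange(row["taxon"], float(row["FAD_Ma"]),
                                         float(row["LAD_Ma"]))
                for _, row in ranges.iterrows()}
    return {r.taxon: r for r in ranges}


def time_calibrate_equal(topology: dendropy.Tree, ranges,
                         root_extension: float = 2.0) -> TimeTree:
    """Time-calibrate a cladogram from stratigraphic ranges, "equal" rule.

    Initial node ages are the maximum first-appearance date (FAD) of their
    descendants; the root is pushed back by ``root_extension`` Myr.  Each
    remaining zero-length branch then takes a share of the nearest
    ancestral positive branch: the node ages along the chain from the top
    of that branch down to the zero branch's child are re-spaced equally,
    which removes the zero while preserving every root-to-tip path.

    Tip ages equal FADs exactly.  ``root_extension=0`` with a zero-length
    basal chain raises, demanding a positive extension.
    """
    if root_extension < 0:
        raise ValueError("root_extension must be >= 0")
    rmap = _as_range_map(ranges)
    tree = topology.clone(depth=1)
    missing = [lf.taxon.label for lf in tree.leaf_node_iter()
               if lf.taxon.label not in rmap]
    if missing:
        raise ValueError(f"no stratigraphic range for: {', '.join(missing)}")

    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            nd.age = rmap[nd.taxon.label].fad
        else:
            nd.age = max(c.age for c in nd.child_nodes())
    root = tree.seed_node
    root.age += root_extension

    # Remove zero branches, shallowest (closest to root) first.  For a zero
    # edge ending at node `nd`, the chain of consecutive zero edges above it
    # plus the nearest ancestral positive branch form one span; its duration
    # is shared equally among all edges on the span by re-spacing the
    # intermediate node ages.  Moved nodes only get older, so no new zeros
    # appear and the loop terminates.
    def _first_zero():
        for node in tree.preorder_node_iter():
            if node.parent_node is not None and node.parent_node.age - node.age <= _AGE_TOL:
                return node
        return None

    while (nd := _first_zero()) is not None:
        chain = [nd]
        anc = nd.parent_node
        while anc.parent_node is not None and anc.parent_node.age - anc.age <= _AGE_TOL:
            chain.append(anc)
            anc = anc.parent_node
        if anc.parent_node is None:
            span_top = anc                      # basal chain: only the root's
        else:                                   # extension provides duration
            span_top = anc.parent_node
            chain.append(anc)                   # the positive branch shares too
        t_hi, t_lo = span_top.age, nd.age
        if t_hi - t_lo <= _AGE_TOL:
            raise ValueError(
                "zero-length basal chain reaches the root; a positive "
                "root_extension is required")
        m = len(chain)                          # edges on the span
        for i, node in enumerate(reversed(chain[1:]), start=1):
            node.age = t_hi - (t_hi - t_lo) * i / m

    # write branch lengths from ages
    for nd in tree.preorder_node_iter():
        if nd.parent_node is not None:
            nd.edge.length = nd.parent_node.age - nd.age
    out = TimeTree(tree=tree, root_age=root.age)
    out.validate()
    return out


# ---------------------------------------------------------------------------
# Specimen selection
# ---------------------------------------------------------------------------

def select_largest_per_taxon(specimens: Sequence[Specimen]) -> list:
    """Keep the largest specimen (by lower jaw length) of each taxon.

    Controls for ontogenetic diet shifts: one adult-most datum per taxon.
    Ties break to the lexicographically first specimen id with a warning.
    A multi-specimen taxon with no jaw lengths at all raises.
    """
    by_taxon: dict = {}
    for sp in specimens:
        by_taxon.setdefault(sp.taxon, []).append(sp)
    out = []
    for taxon, group in by_taxon.items():
        if len(group) == 1:
            out.append(group[0])
            continue
        with_jaw = [sp for sp in group if sp.jaw_length_cm is not None]
        if not with_jaw:
            raise ValueError(f"taxon {taxon!r}: no specimen has a jaw length")
        best = max(sp.jaw_length_cm for sp in with_jaw)
        winners = sorted((sp for sp in with_jaw if sp.jaw_length_cm == best),
                         key=lambda sp: sp.specimen_id)
        if len(winners) > 1:
            warnings.warn(
                f"taxon {taxon!r}: jaw-length tie at {best} cm; "
                f"keeping {winners[0].specimen_id!r} (lexicographic rule)")
        out.append(winners[0])
    return out


# ---------------------------------------------------------------------------
# Brownian-motion covariance machinery
# ---------------------------------------------------------------------------

def _node_key(nd) -> str:
    """Stable node identifier: '|'-joined sorted descendant tip labels.

    Immune to the node-index drift of numbering schemes: the same clade
    gets the same key in any pruning or ladderisation of the tree.
    """
    if nd.is_leaf():
        return nd.taxon.label
    return "|".join(sorted(lf.taxon.label for lf in nd.leaf_iter()))


def _depths(tree: dendropy.Tree) -> None:
    tree.seed_node.depth = 0.0
    for nd in tree.preorder_node_iter():
        if nd.parent_node is not None:
            nd.depth = nd.parent_node.depth + nd.edge.length


def tree_vcv(tree) -> tuple:
    """Brownian-motion variance–covariance matrix of a tree.

    ``C[i, j]`` is the root-to-MRCA path length of tips i and j (their
    shared evolutionary history); the diagonal holds tip depths.  Returns
    ``(labels, C)`` with labels in leaf-iteration order.  Handles
    polytomies natively.
    """
    t = tree.tree if isinstance(tree, TimeTree) else tree
    _depths(t)
    leaves = list(t.leaf_node_iter())
    labels = [lf.taxon.label for lf in leaves]
    index = {id(lf): i for i, lf in enumerate(leaves)}
    n = len(leaves)
    C = np.zeros((n, n))
    for nd in t.postorder_node_iter():
        if nd.is_leaf():
            nd._tipset = [index[id(nd)]]
            C[nd._tipset[0], nd._tipset[0]] = nd.depth
            continue
        kids = nd.child_nodes()
        for a in range(len(kids)):
            for b in range(a + 1, len(kids)):
                ia = np.asarray(kids[a]._tipset)
                ib = np.asarray(kids[b]._tipset)
                C[np.ix_(ia, ib)] = nd.depth
                C[np.ix_(ib, ia)] = nd.depth
        nd._tipset = [i for k in kids for i in k._tipset]
    for nd in t.postorder_node_iter():
        del nd._tipset
    return labels, C


def _align_trait(tree, trait) -> tuple:
    labels, C = tree_vcv(tree)
    if isinstance(trait, pd.Series):
        trait = trait.to_dict()
    missing = [l for l in labels if l not in trait]
    if missing:
        raise ValueError(f"trait missing for tip(s): {', '.join(missing[:5])}")
    x = np.array([float(trait[l]) for l in labels])
    return labels, C, x


def _gls_mean(C_inv: np.ndarray, x: np.ndarray) -> float:
    one = np.ones(len(x))
    return float(one @ C_inv @ x) / float(one @ C_inv @ one)


def blomberg_k(tree, trait, n_perm: int = 999, seed: int | None = None
               ) -> PhyloSignalResult:
    """Blomberg's K with a permutation test.

    K is the ratio of observed MSE0/MSE (tip variance about the
    phylogenetic GLS mean over phylogenetically corrected variance) to its
    Brownian-motion expectation on this tree; K = 1 under BM, K → 0 when
    trait values ignore the tree.  P is the fraction of tip-permuted
    datasets with MSE0/MSE at least as large as observed (``n_perm``
    seeded permutations; ``n_perm=0`` skips the test, e.g. inside
    simulation studies).
    """
    if n_perm and n_perm < 99:
        raise ValueError("n_perm must be >= 99 (or 0 to skip the test)")
    labels, C, x = _align_trait(tree, trait)
    n = len(x)
    t = tree.tree if isinstance(tree, TimeTree) else tree
    internal = [nd for nd in t.preorder_internal_node_iter()
                if nd.parent_node is not None]
    if not internal:
        raise ValueError("star tree: K undefined without internal structure")
    if np.ptp(x) == 0:
        raise ValueError("constant trait: K undefined")
    C_inv = np.linalg.inv(C)
    one = np.ones(n)
    denom_mean = float(one @ C_inv @ one)

    def mse_ratio(vals: np.ndarray) -> np.ndarray:
        # vals: (n,) or (n, m); ratio MSE0/MSE per column
        v = np.atleast_2d(vals.T).T
        a = (one @ C_inv @ v) / denom_mean
        r = v - a
        mse0 = (r * r).sum(axis=0)
        mse = np.einsum("im,im->m", r, C_inv @ r)
        return mse0 / mse

    observed = float(mse_ratio(x)[0])
    expected = (np.trace(C) - n / denom_mean) / (n - 1)
    k = observed / expected
    p = None
    detail = {"n_perm": n_perm, "seed": seed, "expected_ratio": expected}
    if n_perm:
        rng = np.random.default_rng(seed)
        perms = np.column_stack([rng.permutation(x) for _ in range(n_perm)])
        ratios = mse_ratio(perms)
        p = float((1 + np.sum(ratios >= observed)) / (n_perm + 1))
    return PhyloSignalResult(statistic="K", estimate=float(k), p=p, detail=detail)


def _lambda_loglik(lam: float, C: np.ndarray, x: np.ndarray) -> float:
    n = len(x)
    Cl = lam * C
    np.fill_diagonal(Cl, np.diag(C))
    try:
        L = np.linalg.cholesky(Cl)
    except np.linalg.LinAlgError:
        return -np.inf
    logdet = 2.0 * np.log(np.diag(L)).sum()
    one = np.ones(n)
    u = solve_triangular(L, x, lower=True)
    v = solve_triangular(L, one, lower=True)
    a = float(v @ u) / float(v @ v)
    resid = u - a * v
    sigma2 = float(resid @ resid) / n
    if sigma2 <= 0:
        return -np.inf
    return -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)


def pagel_lambda(tree, trait) -> PhyloSignalResult:
    """Pagel's λ by maximum likelihood with a likelihood-ratio test.

    λ multiplies the off-diagonal (shared-history) covariances: λ = 0 means
    tips evolve independently, λ = 1 is Brownian motion on the given tree.
    The ML search is bounded on [0, λ_max] where λ_max keeps the
    transformed covariance positive-definite; P comes from a χ² (1 df)
    likelihood-ratio test against λ = 0.
    """
    labels, C, x = _align_trait(tree, trait)
    if np.ptp(x) == 0:
        raise ValueError("constant trait: lambda undefined")
    off = C[~np.eye(len(x), dtype=bool)]
    lam_max = float(C.max() / off.max()) if off.max() > 0 else 1.0
    res = minimize_scalar(lambda l: -_lambda_loglik(l, C, x),
                          bounds=(0.0, lam_max), method="bounded",
                          options={"xatol": 1e-6})
    lam_hat = float(res.x)
    ll_hat = _lambda_loglik(lam_hat, C, x)
    ll0 = _lambda_loglik(0.0, C, x)
    lr = max(0.0, 2.0 * (ll_hat - ll0))
    p = float(stats.chi2.sf(lr, df=1))
    return PhyloSignalResult(statistic="lambda", estimate=lam_hat, p=p,
                             detail={"loglik": ll_hat, "loglik_lambda0": ll0,
                                     "lambda_max": lam_max})


def ancestral_states(tree, trait) -> TraitReconstruction:
    """ML ancestral states of a continuous trait under Brownian motion.

    Generalised-least-squares formulation: with C the tip covariance
    matrix, the root state is the GLS phylogenetic mean
    x̂ = (1'C⁻¹1)⁻¹ 1'C⁻¹ x, and every internal node k is
    x̂_k = μ̂ + c_k'C⁻¹(x − μ̂1), c_k the node-to-tip shared path lengths.
    Variances use the bias-corrected GLS Brownian rate
    σ̂² = (x − μ̂1)'C⁻¹(x − μ̂1)/(n − 1); 95% CI = estimate ± 1.96 σ.
    Zero-length branches (impossible after equal-scaling) raise.
    """
    labels, C, x = _align_trait(tree, trait)
    t = tree.tree if isinstance(tree, TimeTree) else tree
    for nd in t.preorder_node_iter():
        if nd.parent_node is not None and not nd.edge.length > 0:
            raise ValueError("zero-length branch: ancestral states undefined")
    n = len(x)
    C_inv = np.linalg.inv(C)
    one = np.ones(n)
    mu = _gls_mean(C_inv, x)
    resid = x - mu
    # bias-corrected GLS rate (one df absorbed by the phylogenetic mean);
    # this is the convention of the standard comparative-methods tools
    sigma2 = float(resid @ C_inv @ resid) / (n - 1)
    denom = float(one @ C_inv @ one)

    _depths(t)
    rows = []
    root = t.seed_node
    # shared path length between an internal node k and each tip i:
    # depth of MRCA(k, i) = depth(k) if i descends from k, else depth of the
    # ancestor of k on the path to i.
    for nd in t.preorder_internal_node_iter():
        desc = {lf.taxon.label for lf in nd.leaf_iter()}
        c = np.empty(n)
        for i, lab in enumerate(labels):
            if lab in desc:
                c[i] = nd.depth
            else:
                anc = nd.parent_node
                while lab not in {lf.taxon.label for lf in anc.leaf_iter()}:
                    anc = anc.parent_node
                c[i] = anc.depth
        est = mu + float(c @ C_inv @ resid)
        var = sigma2 * (nd.depth - float(c @ C_inv @ c)
                        + (1.0 - float(one @ C_inv @ c)) ** 2 / denom)
        var = max(var, 0.0)
        half = 1.96 * np.sqrt(var)
        age = getattr(nd, "age", None)
        rows.append({"node": _node_key(nd), "estimate": est, "variance": var,
                     "ci_low": est - half, "ci_high": est + half,
                     "age": age if age is not None else np.nan})
    nodes = pd.DataFrame(rows).set_index("node")
    tips = pd.Series(x, index=labels)
    return TraitReconstruction(nodes=nodes, tips=tips, sigma2=sigma2,
                               root_key=_node_key(root))


def phylo_texture_space(tree, scores: pd.DataFrame, axes=("PC1", "PC2")):
    """Node coordinates and edge list for a phylomorphospace plot.

    Internal nodes sit at their per-axis ancestral-state estimates; edges
    connect parent to child coordinates.  ``scores``: per-tip axis values
    indexed by taxon.
    """
    t = tree.tree if isinstance(tree, TimeTree) else tree
    coords: dict = {}
    for ax in axes:
        rec = ancestral_states(tree, scores[ax])
        for key, est in rec.nodes["estimate"].items():
            coords.setdefault(key, {})[ax] = float(est)
        for lab, val in rec.tips.items():
            coords.setdefault(lab, {})[ax] = float(val)
    nodes = pd.DataFrame.from_dict(coords, orient="index")[list(axes)]
    edges = []
    for nd in t.preorder_node_iter():
        if nd.parent_node is not None:
            edges.append((_node_key(nd.parent_node), _node_key(nd)))
    return nodes, edges


def correlate_scores_with_age(tree: TimeTree, scores) -> dict:
    """Spearman correlation of tip scores with time elapsed from the root.

    Detects directional drift through the texture-dietary space over the
    clade's history.  An ultrametric tree (all tips coeval) is flagged
    undefined.
    """
    from .ordination import spearman
    if isinstance(scores, pd.Series):
        scores = scores.to_dict()
    t = tree.tree
    _depths(t)
    labels = tree.tip_labels()
    missing = [l for l in labels if l not in scores]
    if missing:
        raise ValueError(f"scores missing for tip(s): {', '.join(missing[:5])}")
    depth = {lf.taxon.label: lf.depth for lf in t.leaf_node_iter()}
    ages = np.array([depth[l] for l in labels])
    vals = np.array([float(scores[l]) for l in labels])
    if np.ptp(ages) <= _AGE_TOL:
        return {"rs": float("nan"), "p": float("nan"), "n": len(labels),
                "undefined": True, "reason": "all tips share one age"}
    rs, p, n = spearman(vals, ages)
    return {"rs": rs, "p": p, "n": n, "undefined": False}
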