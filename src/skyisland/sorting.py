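"""Slatkin-Maddison sorting statistic and coalescent model rejection.

The sorting statistic S is the minimum number of character changes
(parsimony steps) of the deme label on a genealogy: a perfectly
geographically sorted tree needs only k-1 changes for k demes, while
incomplete lineage sorting or migration inflates S.  A refugium model is
tested by simulating gene trees within the model, computing S on each, and
asking whether the observed genealogy is more sorted (smaller S) than the
model predicts.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import dendropy
import numpy as np

from .models import GeneTree, RefugiumModel, simulate_gene_tree

__all__ = [
    "SortingTestResult",
    "fitch_steps",
    "deep_coalescences",
    "observed_s",
    "null_distribution",
    "test_model",
]


@dataclass(frozen=True)
class SortingTestResult:
    """Outcome of comparing an observed S value against a model null."""

    model: str
    observed_s: int
    null_mean: float
    null_sd: float
    p_value: float
    n_sims: int
    rejected: bool
    seed: int | None = None

    def __str__(self) -> str:  # report line mirroring the results sentence
        verdict = "rejected" if self.rejected else "not rejected"
        return (f"{self.model}: mean S = {self.null_mean:.1f}, "
                f"SD = {self.null_sd:.1f}, observed S = {self.observed_s}, "
                f"P = {self.p_value:.4g} ({verdict} at alpha = 0.05)")


def _fitch_steps_genetree(tree: GeneTree, state_of_tip: np.ndarray) -> int:
    """Fast bitmask Fitch pass over a binary GeneTree (children precede parents)."""
    n = tree.n_tips
    masks = [0] * (2 * n - 1)
    for tip in range(n):
        masks[tip] = 1 << int(state_of_tip[tip])
    steps = 0
    left, right = tree.left, tree.right
    for j in range(n - 1):
        a = masks[left[j]]
        b = masks[right[j]]
        m = a & b
        if not m:
            m = a | b
            steps += 1
        masks[n + j] = m
    return steps


def _hartigan_steps(tree: dendropy.Tree, states: dict[str, int]) -> int:
    """Minimum unordered-parsimony length on an arbitrary rooted tree.

    Bottom-up state-set pass; at each internal node the states held by the
    greatest number of children form the node set, and every child outside
    it costs one change.  On binary trees this is exactly the Fitch
    intersection/union rule.
    """
    steps = 0
    sets: dict[int, frozenset[int]] = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            lab = nd.taxon.label if nd.taxon else nd.label
            if lab not in states:
                raise KeyError(f"tip {lab!r} has no state assigned")
            sets[id(nd)] = frozenset([states[lab]])
        else:
            counts: Counter[int] = Counter()
            children = nd.child_nodes()
            for ch in children:
                counts.update(sets[id(ch)])
            top = max(counts.values())
            sets[id(nd)] = frozenset(s for s, c in counts.items() if c == top)
            steps += len(children) - top
    return steps


def fitch_steps(tree: GeneTree | dendropy.Tree,
                tip_states: dict[str, str] | None = None) -> int:
    """Parsimony length of a categorical tip character (deme label).

    For a :class:`GeneTree` the deme labels attached to the tips are used
    (``tip_states``, keyed by tip id, overrides them).  For a dendropy tree
    ``tip_states`` maps taxon labels to state labels; polytomies are
    handled exactly (the result is the true minimum over all resolutions).
    """
    if isinstance(tree, GeneTree):
        labels = tree.tip_demes
        if tip_states is not None:
            labels = [tip_states[t] for t in tree.tip_ids]
        cats = sorted(set(labels))
        code = {c: i for i, c in enumerate(cats)}
        arr = np.array([code[s] for s in labels], dtype=np.int64)
        return _fitch_steps_genetree(tree, arr)
    if tip_states is None:
        raise ValueError("tip_states is required for a dendropy tree")
    cats = sorted(set(tip_states.values()))
    code = {c: i for i, c in enumerate(cats)}
    return _hartigan_steps(tree, {k: code[v] for k, v in tip_states.items()})


def deep_coalescences(tree: GeneTree, model: RefugiumModel) -> int:
    """Extra-lineage (deep coalescence) cost of a gene tree within a model.

    Counts, over the model's internal branches, the number of gene lineages
    entering each branch beyond the single lineage a fully sorted genealogy
    would carry.  Secondary discordance measure; the headline statistic is
    :func:`fitch_steps`.
    """
    # number of gene-tree lineages crossing the base of each refugium leaf
    # equals the number of ancestral lineages of that refugium's tips at the
    # leaf's parent divergence time.
    n = tree.n_tips
    parent_of = np.empty(2 * n - 1, dtype=np.int64)
    parent_of[-1] = -1
    for j in range(n - 1):
        parent_of[tree.left[j]] = n + j
        parent_of[tree.right[j]] = n + j

    extra = 0
    for i, name in enumerate(model.names):
        p = model.parent[i]
        if p == -1:
            continue
        t_top = model.node_time[p]
        member_demes = {d for d, r in model.deme_to_refugium.items() if r == name}
        if not member_demes:  # internal model node: demes below it
            member_demes = _demes_below(model, i)
        tips = [t for t in range(n) if tree.tip_demes[t] in member_demes]
        roots = set()
        for t in tips:
            node = t
            while parent_of[node] != -1 and tree.time[parent_of[node]] <= t_top:
                node = parent_of[node]
            roots.add(node)
        extra += len(roots) - 1
    return extra


def _demes_below(model: RefugiumModel, node: int) -> set[str]:
    stack, leaves = [node], set()
    while stack:
        i = stack.pop()
        ch = model.children(i)
        if not ch:
            leaves.add(model.names[i])
        stack.extend(ch)
    return {d for d, r in model.deme_to_refugium.items() if r in leaves}


def observed_s(genealogy: dendropy.Tree | GeneTree,
               deme_assignment: dict[str, str] | None = None) -> int:
    """S of an observed genealogy: parsimony steps of the deme character.

    ``deme_assignment`` maps sample/taxon labels to demes; for a GeneTree
    the attached tip demes are the default.  Raises a labelled error
    listing tips missing from the assignment.
    """
    if isinstance(genealogy, GeneTree):
        return fitch_steps(genealogy, deme_assignment)
    labels = [lf.taxon.label if lf.taxon else lf.label
              for lf in genealogy.leaf_node_iter()]
    deme_assignment = deme_assignment or {}
    resolved: dict[str, str] = {}
    missing = []
    for lab in labels:
        if lab in deme_assignment:
            resolved[lab] = deme_assignment[lab]
        elif "@" in lab:  # sample@deme tip labels
            sid, deme = lab.rsplit("@", 1)
            resolved[lab] = deme_assignment.get(sid, deme)
        else:
            missing.append(lab)
    if missing:
        raise KeyError("tips missing from the deme assignment: "
                       + ", ".join(sorted(missing)[:10]))
    return fitch_steps(genealogy, resolved)


def null_distribution(model: RefugiumModel,
                      deme_sizes: dict[str, int],
                      n_sims: int,
                      rng: np.random.Generator,
                      statistic: str = "fitch") -> dict:
    """Simulate ``n_sims`` gene trees within ``model`` and collect S values.

    ``statistic`` is ``"fitch"`` (deme-character parsimony, default) or
    ``"deep_coalescence"``.  Returns sorted values with their mean and SD.
    """
    if n_sims < 100:
        raise ValueError("n_sims must be at least 100")
    values = np.empty(n_sims, dtype=np.int64)
    demes = sorted(deme_sizes)
    code = {d: i for i, d in enumerate(demes)}
    for r in range(n_sims):
        gt = simulate_gene_tree(model, deme_sizes, rng)
        if statistic == "fitch":
            arr = np.array([code[d] for d in gt.tip_demes], dtype=np.int64)
            values[r] = _fitch_steps_genetree(gt, arr)
        elif statistic == "deep_coalescence":
            values[r] = deep_coalescences(gt, model)
        else:
            raise ValueError(f"unknown statistic {statistic!r}")
    values.sort()
    return {
        "values": values,
        "mean": float(values.mean()),
        "sd": float(values.std(ddof=1)),
        "n_sims": n_sims,
        "statistic": statistic,
    }


def test_model(observed: int, null: dict, model_name: str = "model",
               alpha: float = 0.05, seed: int | None = None) -> SortingTestResult:
    """One-tailed test: is the observed genealogy more sorted than the model?

    p = (1 + #{S_sim <= S_obs}) / (n_sims + 1); ties count toward rejection
    and the add-one correction keeps p positive at finite simulation size.
    """
    values = np.asarray(null["values"])
    if values.size == 0:
        raise ValueError("empty null distribution")
    n = values.size
    p = (1 + int(np.searchsorted(values, observed, side="right"))) / (n + 1)
    p = min(p, 1.0)
    return SortingTestResult(
        model=model_name, observed_s=int(observed),
        null_mean=float(null["mean"]), null_sd=float(null["sd"]),
        p_value=float(p), n_sims=n, rejected=bool(p < alpha), seed=seed)
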