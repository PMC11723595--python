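"""Gumbel perturbation machinery for sampling trees without replacement.

The Gumbel-Max trick: if phi_i are unnormalized log probabilities and
g_i ~ Gumbel(0, 1) i.i.d., then argmax_i (phi_i + g_i) is a draw from
Categorical(softmax(phi)).  Max-stability — max_i Gumbel(phi_i, 1) ~
Gumbel(logsumexp(phi), 1) — lets a search condition the perturbed scores
of a node's extensions on the node's own perturbed score: the children's
perturbed scores are shifted through the truncated-Gumbel CDF so that
their maximum equals the parent's score exactly.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from .phylo_model import MutationTree

__all__ = ["sample_gumbel", "perturb", "shift_perturbed", "node_generator"]


def sample_gumbel(count: int, rng: np.random.Generator) -> np.ndarray:
    """``count`` i.i.d. standard Gumbel(0, 1) draws via -log(-log(U))."""
    u = rng.uniform(low=np.finfo(float).tiny, high=1.0, size=count)
    return -np.log(-np.log(u))


def perturb(phis: Sequence[float], rng: np.random.Generator) -> np.ndarray:
    """Perturbed log probabilities G_i = phi_i + Gumbel(0, 1)."""
    phis = np.asarray(phis, dtype=np.float64)
    return phis + sample_gumbel(phis.size, rng)


def shift_perturbed(T: float, gumbels: Sequence[float]) -> np.ndarray:
    """Condition a sibling set of perturbed scores on the parent's score.

    Given the parent's (shifted) perturbed score ``T`` and the raw
    perturbed scores ``G_i`` of its extensions with ``Z = max_i G_i``,
    returns Gbar_i = -log(exp(-T) - exp(-Z) + exp(-G_i)), the inverse
    truncated-Gumbel CDF transform.  Computed in the numerically stable
    rearrangement Gbar_i = -logaddexp(-T, log1p(-exp(G_i - Z)) - G_i), so
    that max_i Gbar_i == T holds exactly and the ranking of the siblings
    is preserved (the transform is strictly increasing in G_i).
    """
    G = np.asarray(gumbels, dtype=np.float64)
    if G.size == 0:
        raise ValueError("cannot shift an empty candidate set")
    Z = G.max()
    with np.errstate(divide="ignore"):
        w = np.log1p(-np.exp(G - Z))  # -inf at the argmax, by design
    return -np.logaddexp(-T, w - G)


def node_generator(seed: int, tree: MutationTree, salt: Iterable[int] = ()) -> np.random.Generator:
    """Deterministic RNG keyed by a search-tree node's identity.

    The Gumbel noise attached to the extensions of a partial tree is a
    pure function of (seed, partial tree), not of visit order, so runs
    with different beam widths share one noise schedule and an exhaustive
    enumeration can replay it.  Keys feed a SeedSequence, which mixes
    arbitrarily long integer entropy deterministically.
    """
    key = [int(seed) & 0xFFFFFFFF, *(int(x) & 0xFFFFFFFF for x in salt)]
    for v, p in sorted(tree.parent_items()):
        key.append(v)
        key.append(p)
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence(key)))
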