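"""Synthetic haplogroup data with the structure the pipeline assumes.

The generator plants the ground truth each stage is meant to recover:

* *ancestral profiles* — K Dirichlet-distributed frequency profiles over a
  D-label basis (the planted central vectors);
* *populations* — either noisy copies of single profiles (``pure``) or
  convex combinations with recorded mixture weights (``admixed``);
* *individuals* — multinomial draws from each population's distribution,
  with labels optionally extended into deeper subclades (random alternating
  digit/letter runs, mimicking real nomenclature shapes) that the
  cumulating assignment provably maps back to the drawn basis label.

Everything is deterministic given the seed, and every planted quantity is
returned in a :class:`SyntheticTruth` so tests can verify recovery.
"""

from __future__ import annotations

import string
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd

from .freqmatrix import FrequencyMatrix, IndividualTable
from .nomenclature import HgBasis, HgLabel

__all__ = [
    "SyntheticTruth",
    "generate_label_tree",
    "generate_profiles",
    "generate_populations",
    "sample_individuals",
]


@dataclass
class SyntheticTruth:
    """Planted ground truth behind a synthetic dataset."""

    ancestral_profiles: pd.DataFrame  # K x D
    mixture_weights: pd.DataFrame  # P x K
    planted_partition: pd.Series  # population -> source cluster
    label_tree: dict
    seed: Optional[int]


def generate_label_tree(
    D: int, seed: Optional[int] = None, max_depth: int = 3
) -> HgBasis:
    """Generate ``D`` distinct basis labels with depths 1..``max_depth``.

    The tree mimics real nomenclature: top-level letter clades, each with
    digit-numbered subclades and letter-suffixed sub-subclades (A, A1, A1a,
    A2, B, ...), so some basis labels are token-ancestors of others.
    """
    if D < 2:
        raise ValueError("need at least 2 basis labels")
    rng = np.random.default_rng(seed)
    letters = list(string.ascii_uppercase)
    labels: list[str] = []
    li, parents = 0, []
    guard = 0
    while len(labels) < D:
        guard += 1
        if guard > 100 * D:
            raise RuntimeError("label tree generation failed to find enough labels")
        if li < len(letters) and (not parents or rng.random() < 0.4):
            lab = letters[li]
            li += 1
            labels.append(lab)
            parents.append(lab)
        else:
            parent = parents[int(rng.integers(len(parents)))]
            # extend by one level, respecting letter/digit alternation
            last = parent[-1]
            if last.isalpha():
                child = parent + str(int(rng.integers(1, 10)))
            else:
                child = parent + str(rng.choice(list("abcde")))
            if child not in labels and len(child) <= 6:
                labels.append(child)
                if len(HgBasis([child]).labels[0].tokens) < max_depth:
                    parents.append(child)
    return HgBasis.sorted_from(labels[:D])


def generate_profiles(
    K: int, D: int, concentration: float = 0.5, seed: Optional[int] = None
) -> np.ndarray:
    """K Dirichlet-distributed D-dimensional frequency profiles.

    Small ``concentration`` gives spiky, well-separated profiles; large
    values approach the uniform distribution 1/D.
    """
    if K < 1 or D < 2:
        raise ValueError("need K >= 1 and D >= 2")
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    rng = np.random.default_rng(seed)
    return rng.dirichlet(np.full(D, concentration), size=K)


def generate_populations(
    profiles: np.ndarray,
    P: int,
    mixture_mode: str = "pure",
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
    basis: Optional[HgBasis] = None,
    mixture_concentration: float = 0.5,
) -> tuple[FrequencyMatrix, SyntheticTruth]:
    """Draw ``P`` population frequency vectors from planted profiles.

    ``pure`` assigns populations to profiles round-robin and perturbs with
    truncated Gaussian noise (clipped at zero, renormalized); ``admixed``
    draws Dirichlet mixture weights over the profiles.  The partition label
    is the source profile (pure) or the dominant weight (admixed).
    """
    profiles = np.asarray(profiles, dtype=float)
    K, D = profiles.shape
    if P < K:
        raise ValueError(f"P={P} must be >= K={K}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if mixture_mode not in ("pure", "admixed"):
        raise ValueError(f"unknown mixture_mode: {mixture_mode!r}")
    rng = np.random.default_rng(seed)
    if basis is None:
        basis = generate_label_tree(D, seed=rng.integers(2**31))
    if len(basis) != D:
        raise ValueError("basis size must equal profile dimension D")
    pops = [f"pop{i:03d}" for i in range(P)]
    weights = np.zeros((P, K))
    rows = np.zeros((P, D))
    for i in range(P):
        if mixture_mode == "pure":
            src = i % K
            weights[i, src] = 1.0
            row = profiles[src].copy()
        else:
            w = rng.dirichlet(np.full(K, mixture_concentration))
            weights[i] = w
            row = w @ profiles
        if noise_sd > 0:
            row = np.clip(row + rng.normal(0.0, noise_sd, size=D), 0.0, None)
            s = row.sum()
            row = row / s if s > 0 else np.full(D, 1.0 / D)
        rows[i] = row
    cols = basis.raw_labels
    values = pd.DataFrame(rows, index=pd.Index(pops, name="population_id"), columns=cols)
    freq = FrequencyMatrix(
        values=values,
        basis=basis,
        classified_counts=pd.Series(1, index=values.index),
        total_counts=pd.Series(1, index=values.index),
    )
    truth = SyntheticTruth(
        ancestral_profiles=pd.DataFrame(profiles, columns=cols),
        mixture_weights=pd.DataFrame(weights, index=values.index),
        planted_partition=pd.Series(weights.argmax(axis=1), index=values.index),
        label_tree={lab.raw: lab.tokens for lab in basis},
        seed=seed,
    )
    return freq, truth


_LOWER = list(string.ascii_lowercase)


def _extend_label(
    label: HgLabel,
    basis: HgBasis,
    depth_max: int,
    prob: float,
    rng: np.random.Generator,
) -> HgLabel:
    """Extend a basis label into a random deeper subclade whose cumulating
    assignment provably returns the original label.

    The first added token must differ from the next token of every deeper
    basis label descending from ``label``; after that divergence no basis
    member can be a longer prefix of the extended label.
    """
    tokens = list(label.tokens)
    forbidden = {
        b.tokens[label.depth]
        for b in basis
        if b.depth > label.depth and label.is_token_prefix_of(b)
    }
    first_extension = True
    while len(tokens) < depth_max and rng.random() < prob:
        if tokens[-1][-1].isalpha():
            draw = lambda: str(int(rng.integers(1, 100)))
        else:
            draw = lambda: "".join(
                rng.choice(_LOWER, size=int(rng.integers(1, 3)))
            )
        tok = draw()
        if first_extension:
            attempts = 0
            while tok in forbidden:
                tok = draw()
                attempts += 1
                if attempts > 200:  # pathological basis; keep label as-is
                    return HgLabel(tuple(tokens))
            first_extension = False
        tokens.append(tok)
    return HgLabel(tuple(tokens))


def sample_individuals(
    freq: FrequencyMatrix,
    n_per_pop: int,
    subclade_depth_max: int = 7,
    subclade_prob: float = 0.3,
    seed: Optional[int] = None,
) -> IndividualTable:
    """Draw individuals from each population's frequency distribution.

    Each drawn basis label is extended level-by-level with probability
    ``subclade_prob`` into a random legal subclade up to
    ``subclade_depth_max`` tokens; by construction the cumulating
    re-assignment recovers the drawn basis label exactly.
    """
    if n_per_pop < 1:
        raise ValueError("n_per_pop must be >= 1")
    if not 0 <= subclade_prob <= 1:
        raise ValueError("subclade_prob must be in [0, 1]")
    rng = np.random.default_rng(seed)
    basis = freq.basis
    basis_labels = basis.labels
    records = []
    for pop in freq.populations:
        p = freq.values.loc[pop].to_numpy(dtype=float)
        s = p.sum()
        if s <= 0:
            continue
        counts = rng.multinomial(n_per_pop, p / s)
        k = 0
        for j, c in enumerate(counts):
            for _ in range(c):
                lab = _extend_label(
                    basis_labels[j], basis, subclade_depth_max,
                    subclade_prob, rng,
                )
                records.append((f"{pop}_s{k:05d}", pop, lab.raw, lab))
                k += 1
    data = pd.DataFrame(
        records, columns=["sample_id", "population_id", "raw_label", "label"]
    )
    return IndividualTable(data=data)
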