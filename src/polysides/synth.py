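"""Seeded synthetic drug libraries and association tables with planted structure.

The generator mirrors the modeling assumptions of the pipeline so every
stage is testable offline: each drug carries a latent vector u, each side
effect a latent v, and the probability that pair (a, b) exhibits side
effect s is

    P(edge) = sigmoid(<u_a + u_b, v_s> + bias_s)

— additive in the two drugs, matching the e_pair = e1 + e2 fusion, and
low-rank in (pair, side effect), matching the bipartite link-prediction
model. Side-effect base rates get a rank-based offset so the per-side-effect
frequency distribution is heavy-tailed (mean > median), as in real
polypharmacy association tables. Feature matrices are the latents plus
Gaussian noise, so classifier recovery degrades gracefully with noise_sd.

Generated SMILES-like strings have balanced branches and paired ring
digits but are not guaranteed chemically valid; validity is irrelevant to
the pipeline contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataprep import (
    AssociationRecord,
    DrugRecord,
    PairLabelTable,
    SideEffectVocabulary,
    filter_common_side_effects,
    group_to_multilabel,
)

_ATOMS = ["C", "C", "C", "O", "N", "S"]  # carbon-weighted, as in real SMILES


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def gen_drug_library(
    n: int, length_mean: float = 54.0, seed: int = 0, length_sd: float = 15.0
) -> list[DrugRecord]:
    """Generate n SMILES-like strings with lengths around ``length_mean``.

    Branches "(...)" are always closed and ring-bond digits appear in
    matched pairs; output is a pure function of the arguments.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    drugs = []
    for i in range(n):
        target = max(int(rng.normal(length_mean, length_sd)), 3)
        chars: list[str] = []
        open_depth = 0
        ring_open: list[str] = []
        next_ring = 1
        while len(chars) + open_depth + 2 * len(ring_open) < target:
            r = rng.random()
            if r < 0.55 or not chars:
                chars.append(_ATOMS[rng.integers(len(_ATOMS))])
            elif r < 0.65:
                chars.append("=")
                chars.append(_ATOMS[rng.integers(len(_ATOMS))])
            elif r < 0.75 and len(chars) < target - 2:
                chars.append("(")
                open_depth += 1
            elif r < 0.85 and open_depth > 0:
                chars.append(")")
                open_depth -= 1
            elif r < 0.93 and next_ring <= 9:
                chars.append(str(next_ring))
                ring_open.append(str(next_ring))
                next_ring += 1
            elif ring_open:
                chars.append(_ATOMS[rng.integers(len(_ATOMS))])
                chars.append(ring_open.pop())
            else:
                chars.append(_ATOMS[rng.integers(len(_ATOMS))])
        while open_depth > 0:
            chars.append(")")
            open_depth -= 1
        for digit in reversed(ring_open):
            chars.append(_ATOMS[rng.integers(len(_ATOMS))])
            chars.append(digit)
        drugs.append(DrugRecord(drug_id=f"SD{i:04d}", smiles="".join(chars)))
    return drugs


@dataclass
class PlantedModel:
    """Low-rank ground truth behind a synthetic association table."""

    n_drugs: int = 80
    n_side_effects: int = 25
    latent_dim: int = 8
    bias: float = -0.5
    noise_sd: float = 0.1
    skew: float = 0.7  # rank-based frequency-skew exponent; 0 disables
    signal: float = 3.0  # side-effect latent scale; sets planted logit spread
    seed: int = 7
    drug_latents: np.ndarray = field(init=False, repr=False)
    se_latents: np.ndarray = field(init=False, repr=False)
    se_bias: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        rng = np.random.default_rng(self.seed)
        k = self.latent_dim
        # 1/sqrt(k) on the side-effect latents makes the planted logit
        # spread ~sqrt(2)*signal regardless of rank; signal=3 puts the
        # Bayes-optimal AUROC of the fixture around 0.95, so recovery is
        # demanding but attainable.
        self.drug_latents = rng.normal(0, 1.0, (self.n_drugs, k))
        self.se_latents = rng.normal(0, self.signal / np.sqrt(k), (self.n_side_effects, k))
        ranks = np.arange(1, self.n_side_effects + 1, dtype=np.float64)
        self.se_bias = self.bias - self.skew * np.log(rng.permutation(ranks))

    def edge_probability(self, drug_a: int, drug_b: int, se: int) -> float:
        u = self.drug_latents[drug_a] + self.drug_latents[drug_b]
        return float(_sigmoid(u @ self.se_latents[se] + self.se_bias[se]))

    def logit_matrix(self, pairs: np.ndarray) -> np.ndarray:
        """(n_pairs, n_se) matrix of planted logits for index pairs."""
        U = self.drug_latents[pairs[:, 0]] + self.drug_latents[pairs[:, 1]]
        return U @ self.se_latents.T + self.se_bias


@dataclass
class SyntheticDataset:
    drugs: list[DrugRecord]
    associations: list[AssociationRecord]
    truth: PlantedModel
    pair_indices: np.ndarray  # (n_pairs, 2) drug indices, canonical order


def gen_associations(model: PlantedModel, n_pairs: int) -> SyntheticDataset:
    """Sample distinct canonical drug pairs and their planted side-effect edges."""
    max_pairs = model.n_drugs * (model.n_drugs - 1) // 2
    if n_pairs > max_pairs:
        raise ValueError(f"n_pairs={n_pairs} exceeds the {max_pairs} possible pairs")
    rng = np.random.default_rng(model.seed + 1)
    all_pairs = np.array(
        [(a, b) for a in range(model.n_drugs) for b in range(a + 1, model.n_drugs)],
        dtype=np.int64,
    )
    chosen = all_pairs[rng.choice(max_pairs, size=n_pairs, replace=False)]
    probs = _sigmoid(model.logit_matrix(chosen))
    hits = rng.random(probs.shape) < probs

    drugs = gen_drug_library(model.n_drugs, seed=model.seed + 2)
    assoc = [
        AssociationRecord(
            drug_a=drugs[int(a)].drug_id,
            drug_b=drugs[int(b)].drug_id,
            side_effect_id=f"SE{j:03d}",
            side_effect_name=f"synthetic effect {j}",
        )
        for (a, b), row in zip(chosen, hits)
        for j in np.flatnonzero(row)
    ]
    return SyntheticDataset(drugs=drugs, associations=assoc, truth=model, pair_indices=chosen)


def gen_multilabel_fixture(
    model: PlantedModel, n_pairs: int, min_pairs: int = 1
) -> tuple[PairLabelTable, np.ndarray, np.ndarray, SyntheticDataset]:
    """Dataset + noisy feature matrices aligned to the grouped label table.

    Returns (table, pair_features, se_features, dataset). Pair features are
    u_a + u_b plus Gaussian noise of scale ``noise_sd``; side-effect
    features are v_s plus noise. With small noise both classifiers can
    recover the planted structure; with large noise the features carry no
    signal and performance collapses to chance.
    """
    ds = gen_associations(model, n_pairs)
    records, vocab = filter_common_side_effects(ds.associations, min_pairs=min_pairs)
    table = group_to_multilabel(records, vocab)

    rng = np.random.default_rng(model.seed + 3)
    id_to_idx = {d.drug_id: i for i, d in enumerate(ds.drugs)}
    U = np.array(
        [
            model.drug_latents[id_to_idx[a]] + model.drug_latents[id_to_idx[b]]
            for a, b in table.pairs
        ]
    )
    pair_features = U + rng.normal(0, model.noise_sd, U.shape)
    V = np.array([model.se_latents[int(sid[2:])] for sid in vocab.ids])
    se_features = V + rng.normal(0, model.noise_sd, V.shape)
    return table, pair_features, se_features, ds


def standard_fixture(seed: int = 7, n_pairs: int = 400, noise_sd: float = 0.1):
    """The reference recovery fixture: 80 drugs, 25 side effects, rank 8."""
    model = PlantedModel(
        n_drugs=80, n_side_effects=25, latent_dim=8, noise_sd=noise_sd, seed=seed
    )
    return gen_multilabel_fixture(model, n_pairs=n_pairs)


def side_effect_frequencies(associations: list[AssociationRecord]) -> np.ndarray:
    """Distinct-pair counts per side effect (sorted descending)."""
    from collections import defaultdict

    pairs = defaultdict(set)
    for r in associations:
        pairs[r.side_effect_id].add(r.canonical_pair)
    return np.array(sorted((len(v) for v in pairs.values()), reverse=True))
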