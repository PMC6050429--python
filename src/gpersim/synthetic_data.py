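"""Seeded generators for every input the pipeline consumes.

Each generator is a pure function of its parameters and a seed, and
returns its output together with a :class:`SyntheticTruth` recording the
planted ground truth (true rate constants, planted DEGs, the enriched
term, the network stoichiometry), so every downstream stage can be tested
end-to-end without external data.

Seed derivation: every generator builds its own ``numpy`` generator from
``np.random.SeedSequence([seed, _GENERATOR_CODES[name]])``, so fixtures
drawn for different stages from the same base seed are independent but
jointly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .expression_stats import CountTable
from .reaction_network import Model, RateConstant, Reaction, Species
from .simulate import Observable, integrate, observable_timecourse

__all__ = [
    "SyntheticTruth",
    "random_network",
    "noisy_timecourse",
    "synthetic_counts",
    "planted_enrichment",
]

_GENERATOR_CODES = {
    "random_network": 1,
    "noisy_timecourse": 2,
    "synthetic_counts": 3,
    "planted_enrichment": 4,
}


@dataclass
class SyntheticTruth:
    """Ground truth behind one generated artifact."""

    generator: str
    seed: int
    payload: dict = field(default_factory=dict)


def _rng(name: str, seed: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _GENERATOR_CODES[name]]))


# ---------------------------------------------------------------------------
# Networks and time courses
# ---------------------------------------------------------------------------

def random_network(
    n_species: int,
    n_reactions: int,
    frac_reversible: float = 0.3,
    seed: int = 0,
) -> tuple:
    """A random valid mass-action network.

    Reactions are uni- or bimolecular on both sides (reversible reactions
    keep the product side at order ≤ 2 so the reverse constant has a legal
    order); rate constants are log-uniform in [1e-3, 1] (s⁻¹ or μM⁻¹s⁻¹ by
    order); initial concentrations uniform in [0, 2] μM.
    """
    if n_species < 2 or n_reactions < 1:
        raise ValueError("need n_species >= 2 and n_reactions >= 1")
    if not 0.0 <= frac_reversible <= 1.0:
        raise ValueError("frac_reversible must lie in [0, 1]")
    rng = _rng("random_network", seed)
    sids = [f"S{i}" for i in range(n_species)]
    species = [
        Species(id=s, name=s, initial_concentration=float(rng.uniform(0.0, 2.0)))
        for s in sids
    ]

    def draw_side(max_order):
        order = int(rng.integers(1, max_order + 1))
        if order == 2 and rng.random() < 0.25:
            return {str(rng.choice(sids)): 2}
        chosen = rng.choice(sids, size=order, replace=False)
        return {str(s): 1 for s in np.atleast_1d(chosen)}

    def draw_k(order):
        return float(10.0 ** rng.uniform(-3.0, 0.0))

    reactions = []
    for j in range(n_reactions):
        reversible = bool(rng.random() < frac_reversible)
        reactants = draw_side(2)
        while True:
            products = draw_side(2)
            if set(products) != set(reactants):  # avoid no-op reactions
                break
        r_order = sum(reactants.values())
        p_order = sum(products.values())
        kf = RateConstant(f"r{j}_kf", draw_k(r_order), order=r_order)
        kr = RateConstant(f"r{j}_kr", draw_k(p_order), order=p_order) if reversible else None
        reactions.append(
            Reaction(
                id=f"r{j}",
                reactants=reactants,
                products=products,
                kf=kf,
                kr=kr,
                reversible=reversible,
            )
        )
    model = Model(
        name=f"random_network_{seed}",
        species=species,
        reactions=reactions,
        condition_label="synthetic",
    )
    truth = SyntheticTruth(
        generator="random_network",
        seed=seed,
        payload={
            "rate_constants": {
                k.id: k.value
                for r in reactions
                for k in (r.kf, r.kr)
                if k is not None
            },
            "stoichiometry": {
                r.id: (dict(r.reactants), dict(r.products)) for r in reactions
            },
        },
    )
    return model, truth


def noisy_timecourse(
    model: Model,
    true_params: dict,
    t_grid: np.ndarray,
    noise_cv: float = 0.05,
    seed: int = 0,
    observable: Observable | None = None,
) -> tuple:
    """Observable time course at known rate constants with multiplicative
    lognormal noise of coefficient of variation ``noise_cv`` (unit mean).

    Returns (data, truth) where ``data`` has the keys ``times``, ``values``
    and ``observable`` that :func:`gpersim.simulate.fit_rate_constants`
    expects.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    t_grid = np.asarray(t_grid, dtype=float)
    m = model.copy()
    for kid, val in true_params.items():
        m.find_rate_constant(kid).value = float(val)
    if observable is None:
        obs_species = [s.id for s in m.species if not s.is_boundary][-1]
        observable = Observable(name=obs_species, members=[obs_species])
    traj = integrate(m, t_end=float(t_grid[-1]), n_points=max(len(t_grid), 2))
    clean = np.interp(t_grid, traj.times, observable_timecourse(traj, observable))
    if noise_cv == 0:
        values = clean
    else:
        rng = _rng("noisy_timecourse", seed)
        sigma2 = np.log1p(noise_cv ** 2)
        factors = rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=t_grid.shape)
        values = clean * factors
    data = {"times": t_grid, "values": values, "observable": observable}
    truth = SyntheticTruth(
        generator="noisy_timecourse",
        seed=seed,
        payload={"true_params": dict(true_params), "noise_cv": noise_cv},
    )
    return data, truth


# ---------------------------------------------------------------------------
# Expression tables and gene sets
# ---------------------------------------------------------------------------

def synthetic_counts(
    n_genes: int = 1000,
    n_samples_per_group: int = 2,
    n_up: int = 0,
    n_down: int = 0,
    effect_log2fc: float = 2.0,
    dispersion: float = 0.1,
    seed: int = 0,
) -> tuple:
    """Negative-binomial count table for a treated-vs-untreated design.

    The default of two samples per group mirrors a two-biological-replicate
    RNA-seq design.  The first ``n_up`` genes are shifted up and the next
    ``n_down`` down by ``effect_log2fc`` in the treated group; variance is
    μ + dispersion·μ².  Per-gene two-sided p-values come from the exact
    Mann–Whitney U test between groups (a documented rank-based method, so
    downstream calling can be tested without any external DE tool); note
    its granularity: with two samples per group the smallest attainable
    two-sided p is 1/3, so planted effects are only detectable at q-level
    with more replicates.

    Returns (table, stats_frame, truth): the :class:`CountTable`, a
    DataFrame with ``log2_fold_change`` and ``p_value`` per gene, and the
    planted truth.
    """
    if n_up + n_down > n_genes:
        raise ValueError("n_up + n_down exceeds n_genes")
    if dispersion < 0:
        raise ValueError("dispersion must be non-negative")
    rng = _rng("synthetic_counts", seed)
    g = n_genes
    s = n_samples_per_group
    base_mean = rng.lognormal(mean=4.0, sigma=1.0, size=g)  # ~55 reads typical
    length_kb = rng.uniform(0.5, 10.0, size=g)
    fold = np.zeros(g)
    fold[:n_up] = effect_log2fc
    fold[n_up:n_up + n_down] = -effect_log2fc
    mean_u = base_mean
    mean_t = base_mean * 2.0 ** fold

    def draw(mean_vec):
        out = np.empty((g, s))
        for j in range(s):
            if dispersion == 0:
                out[:, j] = rng.poisson(mean_vec)
            else:
                var = mean_vec + dispersion * mean_vec ** 2
                p = mean_vec / var
                n_param = mean_vec ** 2 / (var - mean_vec)
                out[:, j] = rng.negative_binomial(n_param, p)
        return out

    counts = np.hstack([draw(mean_u), draw(mean_t)])
    sample_ids = [f"untreated_{j + 1}" for j in range(s)] + [
        f"treated_{j + 1}" for j in range(s)
    ]
    gene_ids = [f"g{i:05d}" for i in range(g)]
    table = CountTable(
        gene_ids=gene_ids,
        length_kb=length_kb,
        counts=counts,
        mapped_millions=np.maximum(counts.sum(axis=0), 1.0) / 1e6,
        sample_ids=sample_ids,
    )
    u = counts[:, :s]
    t = counts[:, s:]
    lfc = np.log2((t.mean(axis=1) + 0.5) / (u.mean(axis=1) + 0.5))
    pvals = np.ones(g)
    for i in range(g):
        if np.all(u[i] == u[i, 0]) and np.all(t[i] == u[i, 0]):
            pvals[i] = 1.0  # all observations tied; no evidence
            continue
        pvals[i] = mannwhitneyu(
            t[i], u[i], alternative="two-sided",
            method="exact" if s <= 12 else "asymptotic",
        ).pvalue
    frame = pd.DataFrame(
        {"log2_fold_change": lfc, "p_value": np.minimum(pvals, 1.0)}, index=gene_ids
    )
    truth = SyntheticTruth(
        generator="synthetic_counts",
        seed=seed,
        payload={
            "up_genes": gene_ids[:n_up],
            "down_genes": gene_ids[n_up:n_up + n_down],
            "effect_log2fc": effect_log2fc,
            "dispersion": dispersion,
        },
    )
    return table, frame, truth


def planted_enrichment(
    n_background: int = 5000,
    n_terms: int = 50,
    term_size: int = 50,
    list_size: int = 100,
    enrich_factor: float = 5.0,
    seed: int = 0,
) -> tuple:
    """A background, random gene sets and a gene list with one planted term.

    The designated term (the first one) is represented in the gene list at
    ``enrich_factor`` times its chance expectation: the list contains
    exactly ``round(enrich_factor · list_size · term_size / n_background)``
    of its members (stratified draw), with the remainder drawn uniformly
    from non-members.  A factor of 1 leaves the term at its chance level.
    Returns (background, gene_sets, gene_list, truth).
    """
    if term_size > n_background or list_size > n_background:
        raise ValueError("term_size and list_size must not exceed n_background")
    if enrich_factor <= 0:
        raise ValueError("enrich_factor must be positive")
    rng = _rng("planted_enrichment", seed)
    background = [f"g{i:05d}" for i in range(n_background)]
    gene_sets = {}
    member_idx = {}
    for t in range(n_terms):
        members = rng.choice(n_background, size=term_size, replace=False)
        member_idx[f"T{t:03d}"] = members
        gene_sets[f"T{t:03d}"] = [background[i] for i in members]
    planted = "T000"
    k_planted = int(round(enrich_factor * list_size * term_size / n_background))
    k_planted = min(k_planted, term_size, list_size)
    if list_size - k_planted > n_background - term_size:
        raise ValueError("list_size too large for the requested enrichment")
    from_term = rng.choice(member_idx[planted], size=k_planted, replace=False)
    non_members = np.setdiff1d(np.arange(n_background), member_idx[planted])
    from_rest = rng.choice(non_members, size=list_size - k_planted, replace=False)
    chosen = np.concatenate([from_term, from_rest])
    gene_list = [background[i] for i in sorted(chosen)]
    truth = SyntheticTruth(
        generator="planted_enrichment",
        seed=seed,
        payload={"enriched_term": planted, "enrich_factor": enrich_factor},
    )
    return background, gene_sets, gene_list, truth
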