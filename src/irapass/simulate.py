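"""Synthetic immunotherapy cohorts with planted APA ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, at configurable size:

* PDUI values are Beta-distributed proportions (missing completely at
  random at ``missing_rate``);
* planted differential events shift the non-responder group mean by
  ``delta_effect`` (3'-UTR shortening or lengthening);
* APA-factor regulation is planted through a Gaussian copula so that a
  regulated event's PDUI has Spearman correlation ~``regulation_strength``
  with the factor's (log-normal) expression;
* immune-coupled events load on a latent per-sample immune axis that
  separates responders from non-responders, and the member genes of each
  coupled pathway correlate with the event's PDUI with *opposite sign* in
  the two response groups — the signature the scoring system screens for;
* overall survival is exponential with log-hazard proportional to the
  latent axis (negative ``survival_beta``: high-scoring patients live
  longer), with independent exponential censoring.

Randomness is one hierarchical seed stream (``numpy.random.SeedSequence``
spawned per output), so adding an output never perturbs earlier draws and
a config with the same seed reproduces byte-identical tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from irapass.io import (
    ClinicalTable,
    EventId,
    ExpressionTable,
    GeneSetCollection,
    InteractionTable,
    PduiTable,
    ValidationError,
)

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "CohortData",
    "simulate_cohort",
    "simulate_study",
    "simulate_tcell_proportions",
    "TCELL_POPULATIONS",
]

logger = logging.getLogger("irapass")

#: Eight T-cell populations and the state class each belongs to.
TCELL_POPULATIONS: dict[str, str] = {
    "T_naive": "naive",
    "APC_CD8": "activation",
    "Tem": "activation",
    "Tc_CD8": "activation",
    "Th17": "activation",
    "TEMRA": "suppression",
    "Tex_CD8": "suppression",
    "Treg": "suppression",
}


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort.

    Cohort sizes default to 23 responders vs 82 non-responders (the larger
    of the two melanoma ICI cohorts the analysis is built around); the
    remaining defaults are chosen to give realistic bulk RNA-seq scale and
    spread (see docs/methods.md).
    """

    n_responders: int = 23
    n_nonresponders: int = 82
    n_events: int = 2000
    n_diff_events: int = 50
    delta_effect: float = 0.2
    n_genes: int = 3000
    n_factors: int = 98
    n_active_factors: int = 8
    n_regulated_per_factor: int = 20
    hub_factor_targets: int = 60
    regulation_strength: float = 0.6
    n_pathways: int = 25
    pathway_size: tuple[int, int] = (15, 40)
    n_immune_coupled: int = 20
    # per-gene loading of pathway expression on the coupled event's latent;
    # implies within-pathway mean pairwise co-expression of 0.25, the upper
    # end of what real co-expression modules show
    immune_coupling: float = 0.5
    event_latent_loading: float = 0.8
    response_separation: float = 2.0
    survival_baseline_hazard: float = 0.002  # events per day
    survival_beta: float = -0.8
    censor_rate: float = 0.3
    missing_rate: float = 0.05
    concentration: float = 20.0  # Beta a+b; within-group PDUI sd ~ 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_diff_events > self.n_events:
            raise ValidationError("n_diff_events must be <= n_events")
        if self.n_events > self.n_genes:
            raise ValidationError("n_events must be <= n_genes (one event per gene)")
        if not (0 < self.delta_effect <= 1):
            raise ValidationError("delta_effect must be in (0, 1]")
        if not (0 < self.regulation_strength < 1):
            raise ValidationError("regulation_strength must be in (0, 1)")
        if not (0 <= self.censor_rate < 1):
            raise ValidationError("censor_rate must be in [0, 1)")
        if not (0 <= self.missing_rate < 1):
            raise ValidationError("missing_rate must be in [0, 1)")
        if not (0 < self.immune_coupling < 1):
            raise ValidationError("immune_coupling must be in (0, 1)")
        if not (0 < self.event_latent_loading < 1):
            raise ValidationError("event_latent_loading must be in (0, 1)")
        if self.n_immune_coupled > self.n_pathways:
            raise ValidationError("n_immune_coupled must be <= n_pathways")
        needed = (self.n_diff_events + self.n_immune_coupled
                  + self.hub_factor_targets
                  + max(self.n_active_factors - 1, 0) * self.n_regulated_per_factor)
        if needed > self.n_events:
            raise ValidationError(
                f"planted structure needs {needed} events but n_events={self.n_events}"
            )
        for name in ("n_responders", "n_nonresponders", "n_events", "n_genes",
                     "n_factors", "n_pathways"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")

    def null(self) -> "SimulationConfig":
        """Copy of this config with every planted effect switched off."""
        cfg = asdict(self)
        cfg.update(n_diff_events=0, n_immune_coupled=0, n_active_factors=0,
                   response_separation=0.0, survival_beta=0.0)
        cfg["pathway_size"] = tuple(cfg["pathway_size"])
        return SimulationConfig(**cfg)


@dataclass
class SyntheticTruth:
    """Ground-truth record of everything the generator planted."""

    planted_diff_events: dict[EventId, float]          # event -> signed true dPDUI (R - NR)
    factor_targets: dict[str, dict[EventId, int]]      # factor gene -> {event: sign}
    immune_coupled: dict[EventId, tuple[str, int]]     # event -> (pathway, sign)
    latent_score: pd.Series                            # per sample, drives survival
    pathway_membership: dict[str, frozenset[str]]

    def differential_events(self) -> set[EventId]:
        """All events whose PDUI distribution truly differs between groups."""
        return set(self.planted_diff_events) | set(self.immune_coupled)


@dataclass
class CohortData:
    pdui: PduiTable
    expression: ExpressionTable
    clinical: ClinicalTable
    gene_sets: GeneSetCollection
    interactions: InteractionTable
    truth: SyntheticTruth


# ---------------------------------------------------------------------------
# Blueprint: the cohort-independent planted structure
# ---------------------------------------------------------------------------


class _Blueprint:
    """Event/gene/pathway structure shared by all cohorts of one study."""

    def __init__(self, config: SimulationConfig, seed_seq: np.random.SeedSequence):
        c = config
        rng = np.random.default_rng(seed_seq)
        self.config = c

        self.gene_ids = [f"G{i:05d}" for i in range(c.n_genes)]
        self.factor_ids = [f"APAF{i:03d}" for i in range(c.n_factors)]

        # one event per gene, on a random chromosome/coordinate
        chroms = rng.integers(1, 23, size=c.n_events)
        sites = rng.integers(10_000, 5_000_000, size=c.n_events)
        self.events = [
            EventId(self.gene_ids[i], f"chr{chroms[i]}", int(sites[i]))
            for i in range(c.n_events)
        ]

        # disjoint planted classes
        order = rng.permutation(c.n_events)
        cursor = 0

        def take(n):
            nonlocal cursor
            idx = order[cursor:cursor + n]
            cursor += n
            return [self.events[i] for i in idx]

        diff_events = take(c.n_diff_events)
        coupled_events = take(c.n_immune_coupled)
        self.factor_targets: dict[str, dict[EventId, int]] = {}
        for f in range(c.n_active_factors):
            n_t = c.hub_factor_targets if f == 0 else c.n_regulated_per_factor
            targets = take(n_t)
            signs = rng.choice([-1, 1], size=n_t)
            self.factor_targets[self.factor_ids[f]] = dict(zip(targets, signs.tolist()))

        # planted differential events: base mean in [0.3, 0.7] so the full
        # +-delta_effect shift stays inside the unit interval unclipped
        self.diff_mu = rng.uniform(0.3, 0.7, size=c.n_diff_events)
        self.diff_sign = rng.choice([-1, 1], size=c.n_diff_events)
        self.planted_diff = {
            ev: float(s * c.delta_effect) for ev, s in zip(diff_events, self.diff_sign)
        }

        # pathways: the first n_immune_coupled are disjoint blocks reserved
        # for coupling; the remainder are free random draws
        lo, hi = c.pathway_size
        sizes = rng.integers(lo, hi + 1, size=c.n_pathways)
        pool = rng.permutation(c.n_genes)
        self.pathways: dict[str, frozenset[str]] = {}
        pos = 0
        for j in range(c.n_immune_coupled):
            members = pool[pos:pos + sizes[j]]
            pos += sizes[j]
            if pos > c.n_genes:
                raise ValidationError("gene universe too small for coupled pathways")
            self.pathways[f"PATHWAY_{j:03d}"] = frozenset(self.gene_ids[g] for g in members)
        for j in range(c.n_immune_coupled, c.n_pathways):
            members = rng.choice(c.n_genes, size=sizes[j], replace=False)
            self.pathways[f"PATHWAY_{j:03d}"] = frozenset(self.gene_ids[g] for g in members)

        coupled_signs = rng.choice([-1, 1], size=c.n_immune_coupled)
        self.immune_coupled = {
            ev: (f"PATHWAY_{j:03d}", int(coupled_signs[j]))
            for j, ev in enumerate(coupled_events)
        }
        self.coupled_mu = rng.uniform(0.35, 0.65, size=c.n_immune_coupled)

        # base PDUI means for everything not planted differential
        self.base_mu = rng.uniform(0.2, 0.8, size=c.n_events)

        # factor expression scale
        self.factor_log_mean = rng.normal(3.0, 1.0, size=c.n_factors)
        self.gene_log_mean = rng.normal(2.0, 1.5, size=c.n_genes)

        # PPI: random edges among factors plus factor-event_gene pairs, with
        # a spread of scores so the >700 filter is exercised
        n_ppi = 4 * c.n_factors
        nodes = self.factor_ids + [ev.gene_symbol for ev in self.events[: c.n_events // 2]]
        a = rng.choice(len(nodes), size=n_ppi)
        b = rng.choice(len(nodes), size=n_ppi)
        scores = rng.integers(400, 1000, size=n_ppi)
        keep = a != b
        self.ppi = pd.DataFrame({
            "gene_a": [nodes[i] for i in a[keep]],
            "gene_b": [nodes[i] for i in b[keep]],
            "combined_score": scores[keep],
        })


def _beta_params(mu: np.ndarray, concentration: float) -> tuple[np.ndarray, np.ndarray]:
    mu = np.clip(mu, 0.02, 0.98)
    return mu * concentration, (1.0 - mu) * concentration


def _copula_pdui(latent: np.ndarray, mu: float, concentration: float) -> np.ndarray:
    """Map standard-normal latents through a Gaussian copula to Beta(mu, k)."""
    a, b = _beta_params(np.array(mu), concentration)
    u = stats.norm.cdf(latent)
    # keep strictly inside (0,1) so ppf never returns the boundary
    u = np.clip(u, 1e-12, 1 - 1e-12)
    return stats.beta.ppf(u, a, b)


def _simulate_one(config: SimulationConfig, bp: _Blueprint,
                  n_resp: int, n_nonresp: int,
                  seed_seq: np.random.SeedSequence,
                  sample_prefix: str) -> CohortData:
    c = config
    streams = seed_seq.spawn(6)
    rng_lat = np.random.default_rng(streams[0])
    rng_pdui = np.random.default_rng(streams[1])
    rng_expr = np.random.default_rng(streams[2])
    rng_surv = np.random.default_rng(streams[3])
    rng_miss = np.random.default_rng(streams[4])

    n = n_resp + n_nonresp
    sample_ids = [f"{sample_prefix}R{i:03d}" for i in range(n_resp)] + [
        f"{sample_prefix}N{i:03d}" for i in range(n_nonresp)
    ]
    is_resp = np.array([True] * n_resp + [False] * n_nonresp)

    # latent immune axis: separates the response groups
    t = rng_lat.normal(0.0, 1.0, size=n)
    t = t + np.where(is_resp, c.response_separation / 2, -c.response_separation / 2)

    # --- PDUI matrix -----------------------------------------------------
    event_index = {ev: i for i, ev in enumerate(bp.events)}
    pdui = np.empty((c.n_events, n))
    a_all, b_all = _beta_params(bp.base_mu, c.concentration)
    for i in range(c.n_events):
        pdui[i] = rng_pdui.beta(a_all[i], b_all[i], size=n)

    # planted two-group mean shifts (delta = responders - non-responders)
    for j, (ev, true_delta) in enumerate(bp.planted_diff.items()):
        i = event_index[ev]
        mu = bp.diff_mu[j]
        mu_r = mu + true_delta / 2
        mu_n = mu - true_delta / 2
        a_r, b_r = _beta_params(np.array(mu_r), c.concentration)
        a_n, b_n = _beta_params(np.array(mu_n), c.concentration)
        row = np.where(
            is_resp,
            rng_pdui.beta(float(a_r), float(b_r), size=n),
            rng_pdui.beta(float(a_n), float(b_n), size=n),
        )
        pdui[i] = row

    # factor regulation through a Gaussian copula; the latent correlation is
    # back-solved so the PDUI/expression *Spearman* correlation hits target
    rho_latent = 2 * np.sin(np.pi * c.regulation_strength / 6)
    factor_latent = rng_lat.normal(0.0, 1.0, size=(c.n_factors, n))
    for f_name, targets in bp.factor_targets.items():
        f_idx = bp.factor_ids.index(f_name)
        z_f = factor_latent[f_idx]
        for ev, sign in targets.items():
            i = event_index[ev]
            eps = rng_pdui.normal(0.0, 1.0, size=n)
            u = sign * rho_latent * z_f + np.sqrt(1 - rho_latent**2) * eps
            pdui[i] = _copula_pdui(u, bp.base_mu[i], c.concentration)

    # immune-coupled events load on the latent axis
    coupled_latent = {}
    lam = c.event_latent_loading
    for j, (ev, (_pw, sign)) in enumerate(bp.immune_coupled.items()):
        i = event_index[ev]
        eps = rng_pdui.normal(0.0, 1.0, size=n)
        u = sign * lam * t + np.sqrt(1 - lam**2) * eps
        coupled_latent[ev] = u
        pdui[i] = _copula_pdui(u, bp.coupled_mu[j], c.concentration)

    # --- expression matrix ----------------------------------------------
    gene_z = rng_expr.normal(0.0, 1.0, size=(c.n_genes, n))
    # pathway genes of coupled events track the event latent, with the sign
    # flipped between responders and non-responders
    cc = c.immune_coupling
    group_sign = np.where(is_resp, 1.0, -1.0)
    gene_pos = {g: i for i, g in enumerate(bp.gene_ids)}
    for ev, (pw, _sign) in bp.immune_coupled.items():
        u = coupled_latent[ev]
        for g in sorted(bp.pathways[pw]):
            gi = gene_pos[g]
            eps = rng_expr.normal(0.0, 1.0, size=n)
            gene_z[gi] = group_sign * cc * u + np.sqrt(1 - cc**2) * eps
    gene_expr = np.exp(bp.gene_log_mean[:, None] + 0.5 * gene_z)

    factor_expr = np.exp(bp.factor_log_mean[:, None] + 0.5 * factor_latent)
    expr = pd.DataFrame(
        np.vstack([gene_expr, factor_expr]),
        index=bp.gene_ids + bp.factor_ids,
        columns=sample_ids,
    )

    # --- survival ---------------------------------------------------------
    t_std = (t - t.mean()) / (t.std() if t.std() > 0 else 1.0)
    hazard = c.survival_baseline_hazard * np.exp(c.survival_beta * t_std)
    event_time = rng_surv.exponential(1.0 / hazard)
    if c.censor_rate > 0:
        cens_rate = c.survival_baseline_hazard * c.censor_rate / (1 - c.censor_rate)
        censor_time = rng_surv.exponential(1.0 / cens_rate, size=n)
    else:
        censor_time = np.full(n, np.inf)
    os_time = np.maximum(np.minimum(event_time, censor_time), 1.0)
    os_event = (event_time <= censor_time).astype(int)

    clinical = ClinicalTable(pd.DataFrame({
        "response": np.where(is_resp, "PRCR", "PDSD"),
        "os_time": np.round(os_time, 2),
        "os_event": os_event,
    }, index=pd.Index(sample_ids, name="sample_id")))

    # --- missingness ------------------------------------------------------
    if c.missing_rate > 0:
        mask = rng_miss.random(pdui.shape) < c.missing_rate
        pdui = np.where(mask, np.nan, pdui)

    pdui_table = PduiTable(pd.DataFrame(
        pdui, index=[str(ev) for ev in bp.events], columns=sample_ids
    ))

    truth = SyntheticTruth(
        planted_diff_events=dict(bp.planted_diff),
        factor_targets={f: dict(t_) for f, t_ in bp.factor_targets.items()},
        immune_coupled=dict(bp.immune_coupled),
        latent_score=pd.Series(t, index=sample_ids, name="latent_score"),
        pathway_membership=dict(bp.pathways),
    )

    return CohortData(
        pdui=pdui_table,
        expression=ExpressionTable(expr),
        clinical=clinical,
        gene_sets=GeneSetCollection(dict(bp.pathways), provenance="synthetic"),
        interactions=InteractionTable(bp.ppi.copy()),
        truth=truth,
    )


def simulate_cohort(config: SimulationConfig) -> CohortData:
    """Generate one cohort (tables + ground truth) from ``config.seed``."""
    root = np.random.SeedSequence(config.seed)
    bp_seed, cohort_seed = root.spawn(2)
    bp = _Blueprint(config, bp_seed)
    return _simulate_one(config, bp, config.n_responders, config.n_nonresponders,
                         cohort_seed, sample_prefix="S")


def simulate_study(config: SimulationConfig,
                   cohort_sizes: tuple[tuple[int, int], ...] = ((14, 13), (23, 82)),
                   ) -> list[CohortData]:
    """Generate multiple cohorts sharing one planted structure.

    Default sizes mirror the two discovery cohorts (14 vs 13 responders/
    non-responders, and 23 vs 82).  Event identities, pathway memberships
    and planted couplings are identical across cohorts; samples are fresh.
    """
    root = np.random.SeedSequence(config.seed)
    seeds = root.spawn(1 + len(cohort_sizes))
    bp = _Blueprint(config, seeds[0])
    return [
        _simulate_one(config, bp, n_r, n_n, seeds[k + 1], sample_prefix=f"C{k + 1}_")
        for k, (n_r, n_n) in enumerate(cohort_sizes)
    ]


def simulate_tcell_proportions(n_samples: int,
                               subgroup_mix: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3),
                               alpha_in: float = 6.0,
                               alpha_out: float = 1.0,
                               seed: int = 0) -> tuple[pd.DataFrame, pd.Series]:
    """Samples x 8 T-cell population fractions, with archetype ground truth.

    ``subgroup_mix`` gives the (TA, TS, TN) archetype frequencies.  Each
    sample's fractions are Dirichlet with concentration ``alpha_in`` on the
    populations of its archetype's class and ``alpha_out`` elsewhere (the
    naive class holds a single population, so its in-class concentration is
    doubled to keep the class sums comparable).  Rows sum to one exactly.
    """
    mix = np.asarray(subgroup_mix, dtype=float)
    if np.any(mix < 0):
        raise ValidationError("subgroup_mix fractions must be non-negative")
    if not np.isclose(mix.sum(), 1.0):
        raise ValidationError("subgroup_mix must sum to 1")
    rng = np.random.default_rng(seed)
    archetypes = ("TA", "TS", "TN")
    class_of_archetype = {"TA": "activation", "TS": "suppression", "TN": "naive"}
    pops = list(TCELL_POPULATIONS)
    labels = rng.choice(3, size=n_samples, p=mix)
    rows = np.empty((n_samples, len(pops)))
    for s in range(n_samples):
        cls = class_of_archetype[archetypes[labels[s]]]
        alpha = np.array([
            alpha_in if TCELL_POPULATIONS[p] == cls else alpha_out for p in pops
        ])
        n_in = sum(TCELL_POPULATIONS[p] == cls for p in pops)
        if n_in == 1:
            alpha[[TCELL_POPULATIONS[p] == cls for p in pops]] *= 2
        rows[s] = rng.dirichlet(alpha)
    props = pd.DataFrame(rows, columns=pops,
                         index=[f"S{i:03d}" for i in range(n_samples)])
    truth = pd.Series([archetypes[k] for k in labels], index=props.index,
                      name="archetype")
    return props, truth
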