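"""Synthetic caged-biomonitoring studies with known ground truth.

The generative model mirrors the structure under which PLS-based contaminant
selection is the right analysis: a small number of latent exposure factors
vary between sites; a subset of contaminants ("active") and a subset of
metabolites ("responsive") both load on those factors, so their site profiles
covary; everything else is positive right-skewed noise.  Concentrations and
abundances are lognormal, below-detection-limit censoring is applied per
analyte, and multiplicative run-day block effects contaminate all metabolites
in a block (removed later by block-wise median normalization).

Event-to-event concentration noise is modelled as basin-wide (shared across
sites within a sampling event), so contaminants without a factor loading
aggregate to site-constant maxima; see docs/methods.md for what this does
and does not emulate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .datamodel import ContaminantPanel, MetaboliteMatrix
from .errors import ConfigurationError, ValidationError

#: sd of the lognormal event-to-event noise on contaminant concentrations.
EVENT_NOISE_SD = 0.3

#: class mix of the target panel (hormones : pesticides : PPCPs), study-like.
_CLASS_WEIGHTS = {"hormone": 14, "pesticide": 62, "ppcp": 144}


@dataclass(frozen=True)
class SimulationConfig:
    """Study-shaped defaults: 4 sites x 6 events x 220 analytes of which 60
    are ever detected (15 driven by the latent exposure factors), 8 animals
    per site x 186 metabolites of which 30 respond to the same factors."""

    n_sites: int = 4
    n_events_per_site: int = 6
    n_analytes: int = 220
    frac_never_detected: float = 160 / 220
    n_active_contaminants: int = 15
    n_samples_per_site: int = 8
    n_metabolites: int = 186
    n_responsive_metabolites: int = 30
    n_latent_factors: int = 2
    effect_size: float = 2.0
    lod_quantile: float = 0.25
    block_effect_sd: float = 0.2
    noise_sd: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if self.n_sites < 2:
            raise ConfigurationError("need at least 2 sites")
        if self.n_events_per_site < 1:
            raise ConfigurationError("need at least 1 sampling event per site")
        if not 0.0 <= self.frac_never_detected <= 1.0:
            raise ConfigurationError("frac_never_detected must be in [0, 1]")
        if not 0.0 <= self.lod_quantile < 1.0:
            raise ConfigurationError("lod_quantile must be in [0, 1)")
        if self.n_latent_factors < 1:
            raise ConfigurationError("need at least 1 latent factor")
        if self.effect_size < 0:
            raise ConfigurationError("effect_size must be >= 0")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be > 0")
        if self.block_effect_sd < 0:
            raise ConfigurationError("block_effect_sd must be >= 0")
        n_detected = self.n_analytes - round(self.n_analytes * self.frac_never_detected)
        if self.n_active_contaminants > n_detected:
            raise ConfigurationError(
                f"n_active_contaminants={self.n_active_contaminants} exceeds the "
                f"{n_detected} detected analytes implied by frac_never_detected"
            )
        if self.n_responsive_metabolites > self.n_metabolites:
            raise ConfigurationError("n_responsive_metabolites exceeds n_metabolites")


@dataclass
class GroundTruth:
    """What the generator planted, for recovery scoring."""

    active_contaminants: set[str]
    responsive_metabolites: set[str]
    site_factor_scores: pd.DataFrame          # sites x factors
    contaminant_loadings: pd.DataFrame        # active analytes x factors
    metabolite_loadings: pd.DataFrame         # responsive metabolites x factors
    config: SimulationConfig

    def to_dict(self) -> dict:
        return {
            "active_contaminants": sorted(self.active_contaminants),
            "responsive_metabolites": sorted(self.responsive_metabolites),
            "site_factor_scores": self.site_factor_scores.to_dict(),
            "contaminant_loadings": self.contaminant_loadings.to_dict(),
            "metabolite_loadings": self.metabolite_loadings.to_dict(),
            "config": asdict(self.config),
        }


@dataclass
class CensoringResult:
    panel: ContaminantPanel
    n_censored: int


def apply_lod_censoring(
    panel: ContaminantPanel, lods: Mapping[str, float]
) -> CensoringResult:
    """Censor records whose concentration falls below the analyte's limit.

    A value *equal to or above* its detection limit counts as detected, so
    only strictly smaller concentrations are replaced by the below-limit
    marker.  Already-censored records are left untouched.
    """
    df = panel.records.copy()
    present = set(df["analyte"])
    missing = present - set(lods)
    if missing:
        raise ValidationError(f"no detection limit for analyte(s): {sorted(missing)}")
    lod = df["analyte"].map(lods).astype(float)
    newly = ~df["censored"] & (df["concentration"] < lod)
    df.loc[newly, "censored"] = True
    df.loc[newly, "concentration"] = np.nan
    df["detection_limit"] = lod
    out = ContaminantPanel(records=df, site_temperature=dict(panel.site_temperature))
    return CensoringResult(panel=out, n_censored=int(newly.sum()))


def _assign_classes(analytes: list[str]) -> list[str]:
    """Deterministic class labels in study-like proportions."""
    total = sum(_CLASS_WEIGHTS.values())
    n = len(analytes)
    counts = {c: int(round(n * w / total)) for c, w in _CLASS_WEIGHTS.items()}
    while sum(counts.values()) < n:
        counts["ppcp"] += 1
    while sum(counts.values()) > n:
        counts["ppcp"] -= 1
    labels: list[str] = []
    for cls in ("hormone", "pesticide", "ppcp"):
        labels.extend([cls] * counts[cls])
    return labels[:n]


def simulate_study(
    config: SimulationConfig,
) -> tuple[ContaminantPanel, MetaboliteMatrix, GroundTruth]:
    """Generate a complete synthetic study (panel, metabolites, truth).

    Identical config (including seed) gives identical output.  Sub-streams
    are spawned per data block so enlarging the metabolite block never
    perturbs the contaminant draws.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_fac, rng_cont, rng_temp, rng_met, rng_blk = (
        np.random.default_rng(child) for child in ss.spawn(5)
    )

    sites = [f"S{i + 1}" for i in range(config.n_sites)]
    events = [f"E{j + 1}" for j in range(config.n_events_per_site)]
    width = len(str(config.n_analytes))
    analytes = [f"A{i + 1:0{width}d}" for i in range(config.n_analytes)]
    classes = dict(zip(analytes, _assign_classes(analytes)))

    n_never = round(config.n_analytes * config.frac_never_detected)
    n_detected = config.n_analytes - n_never
    perm = rng_cont.permutation(config.n_analytes)
    detected = [analytes[i] for i in sorted(perm[:n_detected])]
    never = [analytes[i] for i in sorted(perm[n_detected:])]
    active = sorted(rng_cont.choice(detected, size=config.n_active_contaminants,
                                    replace=False).tolist())
    active_set = set(active)

    q = config.n_latent_factors
    Z = rng_fac.normal(size=(config.n_sites, q))          # site factor scores

    # log site-level mean concentration per analyte: active analytes load on
    # the factors; inert ones are site-constant.
    intercept = rng_cont.normal(0.0, 0.5, size=config.n_analytes)
    loadings = np.zeros((config.n_analytes, q))
    act_idx = [analytes.index(a) for a in active]
    loadings[act_idx] = rng_cont.normal(0.0, 1.0, size=(len(act_idx), q))
    log_site_mean = intercept[:, None] + loadings @ Z.T   # analytes x sites

    # Event-to-event variation is basin-wide: sampling events are common
    # dates, and flow/weather-driven concentration fluctuation is shared by
    # all sites.  Site-to-site differences therefore come only from the
    # latent exposure factors (active analytes); inert analytes aggregate to
    # identical per-site maxima.
    event_noise = rng_cont.normal(0.0, EVENT_NOISE_SD,
                                  size=(config.n_analytes, config.n_events_per_site))
    conc = np.exp(np.repeat(log_site_mean, config.n_events_per_site, axis=1)
                  + np.tile(event_noise, (1, config.n_sites)))  # analytes x (site*event)

    # Per-analyte detection limits: detected analytes censored at the chosen
    # quantile of their own event values; never-detected analytes get a limit
    # above their largest value so every event is censored.
    lods: dict[str, float] = {}
    for i, a in enumerate(analytes):
        vals = conc[i]
        if a in set(never):
            lods[a] = float(vals.max()) * 1.5
        else:
            lod = float(np.quantile(vals, config.lod_quantile))
            # keep the analyte detectable: at least the max stays >= LOD
            lods[a] = min(lod, float(vals.max()))

    rows = []
    for i, a in enumerate(analytes):
        col = 0
        for s in sites:
            for e in events:
                rows.append((s, e, a, classes[a], conc[i, col], False, lods[a]))
                col += 1
    records = pd.DataFrame(rows, columns=["site", "event", "analyte",
                                          "contaminant_class", "concentration",
                                          "censored", "detection_limit"])

    site_temperature = {}
    for k, s in enumerate(sites):
        mean_t = 20.0 + 2.0 * Z[k, 0]
        site_temperature[s] = (
            mean_t + rng_temp.normal(0.0, 0.5, size=config.n_events_per_site)
        ).tolist()

    panel = ContaminantPanel(records=records, site_temperature=site_temperature)
    panel = apply_lod_censoring(panel, lods).panel

    # metabolites ----------------------------------------------------------
    n_samples = config.n_sites * config.n_samples_per_site
    sample_sites = np.repeat(np.arange(config.n_sites), config.n_samples_per_site)
    width_m = len(str(config.n_metabolites))
    metabolites = [f"M{i + 1:0{width_m}d}" for i in range(config.n_metabolites)]
    resp_idx = np.sort(rng_met.choice(config.n_metabolites,
                                      size=config.n_responsive_metabolites,
                                      replace=False))
    responsive = [metabolites[i] for i in resp_idx]

    base = rng_met.normal(0.0, 0.3, size=config.n_metabolites)
    G = rng_met.normal(0.0, 1.0, size=(config.n_responsive_metabolites, q))
    signal_site = G @ Z.T                                 # responsive x sites
    # scale so site-driven sd / residual sd = effect_size on the log scale
    sd_site = signal_site[:, sample_sites].std(axis=1, ddof=0)
    scale = np.where(sd_site > 0,
                     config.effect_size * config.noise_sd / np.where(sd_site > 0, sd_site, 1.0),
                     0.0)
    log_x = np.tile(base[None, :], (n_samples, 1))
    log_x += rng_met.normal(0.0, config.noise_sd,
                            size=(n_samples, config.n_metabolites))
    log_x[:, resp_idx] += (scale[:, None] * signal_site)[:, sample_sites].T

    sample_ids = [f"{sites[s]}_a{k % config.n_samples_per_site + 1}"
                  for k, s in enumerate(sample_sites)]
    blocks = np.array([f"day{k % 2 + 1}" for k in range(n_samples)])
    block_factor = rng_blk.normal(0.0, config.block_effect_sd,
                                  size=(2, config.n_metabolites))
    for b, name in enumerate(("day1", "day2")):
        log_x[blocks == name] += block_factor[b]

    values = pd.DataFrame(np.exp(log_x),
                          index=pd.Index(sample_ids, name="sample_id"),
                          columns=metabolites)
    site_of = pd.Series([sites[s] for s in sample_sites], index=values.index,
                        name="site")
    block_of = pd.Series(blocks, index=values.index, name="block")
    matrix = MetaboliteMatrix(values=values, site_of=site_of,
                              normalized=False, block_of=block_of)

    truth = GroundTruth(
        active_contaminants=active_set,
        responsive_metabolites=set(responsive),
        site_factor_scores=pd.DataFrame(Z, index=sites,
                                        columns=[f"factor{j + 1}" for j in range(q)]),
        contaminant_loadings=pd.DataFrame(loadings[act_idx], index=active,
                                          columns=[f"factor{j + 1}" for j in range(q)]),
        metabolite_loadings=pd.DataFrame(G, index=responsive,
                                         columns=[f"factor{j + 1}" for j in range(q)]),
        config=config,
    )
    return panel, matrix, truth
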