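"""Synthetic study-design generators with known ground truth.

Everything the pipeline consumes can be generated here, emulating a
two-genotype Drosophila feeding study: a metabolite panel measured across
tissues, ages and treatments with extraction blanks and contaminant
features; Gompertz-distributed lifespans with right-censoring; and qPCR
cycle thresholds with known relative expression.  All generators are pure
functions of (config, seed) so every downstream statistic can be checked
against the truth records.

Metabolite model
----------------
Intensities are log-normal around a per-metabolite baseline ``b_i`` (log10
scale).  A metabolite flagged as affected for a (tissue, genotype) carries
a treatment x age *interaction*: treated samples gain
``effect_size * age_ramp`` on the log10 scale, where the ramp rises
linearly from 0 at the first age point to 1 at the last.  The ramp makes
the signal a genuine interaction (slope difference between arms) rather
than a treatment main effect, which is what the per-metabolite two-factor
test downstream is designed to detect.  Blanks sit at ``blank_level`` of
baseline; contaminant features sit at blank level in study samples too, so
the blank-ratio filter has true positives and true negatives to find.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import (AbundanceMatrix, ConfigError, PathwayMap, TISSUES,
                 validate_ct, validate_sample_sheet, validate_survival)

__all__ = [
    "GeneratorConfig", "SyntheticTruth", "SurvivalGroupSpec",
    "generate_metabolomics", "generate_survival", "generate_ct",
    "gompertz_median", "multiplier_for_median_ratio",
]


@dataclass
class GeneratorConfig:
    """Design parameters of the synthetic metabolomics study.

    Defaults mirror the study design being emulated: a 218-metabolite
    panel over 23 pathways, 4 tissues x 2 genotypes x 2 treatments x
    4 ages x 3 biological replicates, plus extraction blanks and a handful
    of blank-level contaminant features.
    """

    n_metabolites: int = 218
    n_pathways: int = 23
    tissues: Sequence[str] = TISSUES
    ages: Sequence[int] = (7, 14, 19, 24)
    n_replicates: int = 3
    genotypes: Sequence[str] = ("EY05103", "Delta174")
    baseline_log10_range: tuple[float, float] = (3.0, 6.0)
    fraction_affected: float = 0.2
    overlap_fraction: float = 0.5
    effect_size: float = 0.5
    noise_sd: float = 0.1
    blank_level: float = 1.0 / 20.0
    n_blanks: int = 3
    n_contaminants: int = 10
    concentrate_in_pathways: int = 0    # >0: draw affected ids from the
                                        # first k pathways (enrichment truth)
    multi_pathway_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fraction_affected", "overlap_fraction", "blank_level",
                     "multi_pathway_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must be in [0,1], got {v}")
        if self.effect_size < 0:
            raise ConfigError("effect_size must be >= 0")
        for name in ("n_metabolites", "n_pathways", "n_replicates",
                     "n_blanks"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if len(self.ages) < 2:
            raise ConfigError("need at least two age points")
        if self.concentrate_in_pathways > self.n_pathways:
            raise ConfigError("concentrate_in_pathways exceeds n_pathways")


@dataclass
class SyntheticTruth:
    """Ground truth written alongside every generated dataset."""

    affected: dict[tuple[str, str], set[str]] = field(default_factory=dict)
    baselines: dict[str, float] = field(default_factory=dict)
    effect_size: float = 0.0
    contaminants: set[str] = field(default_factory=set)
    enriched_pathways: list[str] = field(default_factory=list)
    survival_params: dict[str, dict[str, float]] = field(default_factory=dict)
    true_median: dict[str, float] = field(default_factory=dict)
    true_rq: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# metabolomics
# ---------------------------------------------------------------------------

def _assign_pathways(metabolites: list[str], config: GeneratorConfig,
                     rng: np.random.Generator) -> PathwayMap:
    """Round-robin primary assignment (covers every pathway), plus a random
    secondary membership for a fraction of the panel."""
    members: dict[str, set[str]] = {
        f"PW{k + 1:02d}": set() for k in range(config.n_pathways)}
    pids = sorted(members)
    for i, m in enumerate(metabolites):
        members[pids[i % config.n_pathways]].add(m)
    n_multi = int(round(config.multi_pathway_fraction * len(metabolites)))
    for m in rng.choice(metabolites, size=n_multi, replace=False):
        members[pids[rng.integers(config.n_pathways)]].add(str(m))
    descriptions = {p: f"synthetic pathway {p}" for p in pids}
    return PathwayMap({p: s for p, s in members.items() if s}, descriptions)


def _affected_sets(metabolites: list[str], pathways: PathwayMap,
                   config: GeneratorConfig, rng: np.random.Generator,
                   ) -> tuple[dict[tuple[str, str], set[str]], list[str]]:
    """Pick affected metabolites per (tissue, genotype) honouring the
    cross-genotype overlap fraction; optionally concentrate them in the
    first ``concentrate_in_pathways`` pathways."""
    n_aff = int(round(config.fraction_affected * len(metabolites)))
    n_shared = int(round(config.overlap_fraction * n_aff))
    enriched: list[str] = []
    pool = list(metabolites)
    if config.concentrate_in_pathways:
        # Round-robin over the designated pathways so the affected sets
        # spread evenly across them, skipping members that also belong to
        # a non-designated pathway (their signal would leak out of the
        # designated set via double counting).
        pids = sorted(pathways.members)
        enriched = pids[:config.concentrate_in_pathways]
        outside = set().union(
            set(), *(pathways.members[p]
                     for p in pids[config.concentrate_in_pathways:]))
        queues = [list(rng.permutation(sorted(
            pathways.members[p] - outside))) for p in enriched]
        preferred: list[str] = []
        while any(queues):
            for q in queues:
                if q:
                    preferred.append(q.pop())
        rest = sorted(set(metabolites) - set(preferred))
        pool = preferred + list(rng.permutation(rest))
    affected: dict[tuple[str, str], set[str]] = {}
    for tissue in config.tissues:
        if config.concentrate_in_pathways:
            order = pool            # preferred-first, fixed across draws
        else:
            order = list(rng.permutation(pool))
        shared = set(order[:n_shared])
        g_a = shared | set(order[n_shared:n_aff])
        g_b = shared | set(order[n_aff:2 * n_aff - n_shared])
        affected[(tissue, str(config.genotypes[0]))] = set(map(str, g_a))
        affected[(tissue, str(config.genotypes[1]))] = set(map(str, g_b))
    return affected, enriched


def generate_metabolomics(config: GeneratorConfig | None = None, **kw,
                          ) -> tuple[AbundanceMatrix, pd.DataFrame,
                                     PathwayMap, SyntheticTruth]:
    """Generate (AbundanceMatrix, sample sheet, PathwayMap, SyntheticTruth).

    Deterministic given ``config.seed``.  The matrix includes the
    extraction blanks; the sheet is also reachable as
    ``matrix.sample_sheet``.
    """
    if config is None:
        config = GeneratorConfig(**kw)
    elif kw:
        raise ConfigError("pass either a GeneratorConfig or keywords")
    rng = np.random.default_rng(config.seed)

    metabolites = [f"M{i + 1:03d}" for i in range(config.n_metabolites)]
    contaminants = [f"C{i + 1:03d}" for i in range(config.n_contaminants)]
    panel = metabolites + contaminants

    pathways = _assign_pathways(metabolites, config, rng)
    affected, enriched = _affected_sets(metabolites, pathways, config, rng)

    lo, hi = config.baseline_log10_range
    baseline = rng.uniform(lo, hi, size=len(panel))
    log_blank_offset = math.log10(config.blank_level)

    rows = []
    sample_ids: list[str] = []
    ramp = {age: i / (len(config.ages) - 1)
            for i, age in enumerate(config.ages)}
    for tissue in config.tissues:
        for genotype in config.genotypes:
            for treatment in ("control", "DA"):
                for age in config.ages:
                    for rep in range(1, config.n_replicates + 1):
                        sid = (f"{tissue}_{genotype}_{treatment}"
                               f"_d{age}_r{rep}")
                        sample_ids.append(sid)
                        rows.append((sid, tissue, genotype, treatment,
                                     age, rep, False))
    for b in range(1, config.n_blanks + 1):
        sid = f"blank_r{b}"
        sample_ids.append(sid)
        rows.append((sid, "", "", "", 0, b, True))
    sheet = validate_sample_sheet(pd.DataFrame(
        rows, columns=["sample_id", "tissue", "genotype", "treatment",
                       "age_days", "replicate", "is_blank"]))

    is_contaminant = np.array([m in set(contaminants) for m in panel])
    log10 = np.empty((len(panel), len(sample_ids)))
    for j, sid in enumerate(sample_ids):
        row = sheet.loc[sid]
        mu = baseline.copy()
        if row["is_blank"]:
            mu = mu + log_blank_offset
        else:
            mu = np.where(is_contaminant, mu + log_blank_offset, mu)
            key = (row["tissue"], row["genotype"])
            if row["treatment"] == "DA" and key in affected:
                hit = np.array([m in affected[key] for m in panel])
                mu = mu + hit * config.effect_size * ramp[row["age_days"]]
        log10[:, j] = mu
    log10 += rng.normal(0.0, config.noise_sd, size=log10.shape)

    matrix = AbundanceMatrix(panel, sample_ids, 10.0 ** log10, sheet)
    truth = SyntheticTruth(
        affected=affected,
        baselines=dict(zip(panel, baseline)),
        effect_size=config.effect_size,
        contaminants=set(contaminants),
        enriched_pathways=enriched,
    )
    return matrix, sheet, pathways, truth


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

@dataclass
class SurvivalGroupSpec:
    """One study arm under Gompertz mortality.

    The hazard is ``h(t) = a * exp(b * t) * hazard_multiplier``; ``a`` is
    the baseline mortality rate (1/day), ``b`` the ageing rate (1/day).
    Defaults give a control arm with a 40-day analytic median, a typical
    short-lived mutant fly line.
    """

    a: float = 2.584e-4
    b: float = 0.15
    hazard_multiplier: float = 1.0
    n: int = 150
    censor_prob: float = 0.0

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0 or self.hazard_multiplier <= 0:
            raise ConfigError("Gompertz parameters must be positive")
        if self.n <= 0:
            raise ConfigError("arm size n must be positive")
        if not 0 <= self.censor_prob < 1:
            raise ConfigError("censor_prob must be in [0,1)")


def gompertz_median(a: float, b: float, multiplier: float = 1.0) -> float:
    """Analytic median of the Gompertz law h(t) = a*multiplier*exp(b t)."""
    return math.log1p(b * math.log(2.0) / (a * multiplier)) / b


def multiplier_for_median_ratio(a: float, b: float, ratio: float) -> float:
    """Hazard multiplier that scales the analytic median by ``ratio``
    (ratio > 1 means a longer-lived arm, i.e. multiplier < 1)."""
    m_target = gompertz_median(a, b) * ratio
    return b * math.log(2.0) / (a * math.expm1(b * m_target))


def generate_survival(group_specs: Mapping[str, SurvivalGroupSpec | dict],
                      seed: int = 0,
                      ) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Draw per-individual event/censor times for each study arm.

    Censored individuals get a uniform censoring time before their (latent)
    death time.  Returns the records table plus truth holding each group's
    parameters and analytic median.
    """
    rng = np.random.default_rng(seed)
    truth = SyntheticTruth()
    frames = []
    for group in sorted(group_specs):
        spec = group_specs[group]
        if isinstance(spec, dict):
            spec = SurvivalGroupSpec(**spec)
        c = spec.a * spec.hazard_multiplier / spec.b
        death = stats.gompertz(c, scale=1.0 / spec.b).rvs(
            size=spec.n, random_state=rng)
        censored = rng.random(spec.n) < spec.censor_prob
        time = np.where(censored, rng.uniform(0.0, death), death)
        time = np.maximum(time, 1e-9)
        frames.append(pd.DataFrame({
            "individual_id": [f"{group}_{i + 1}" for i in range(spec.n)],
            "group": group,
            "time": time,
            "status": np.where(censored, "censored", "dead"),
        }))
        truth.survival_params[group] = {
            "a": spec.a, "b": spec.b,
            "hazard_multiplier": spec.hazard_multiplier,
            "n": spec.n, "censor_prob": spec.censor_prob}
        truth.true_median[group] = gompertz_median(
            spec.a, spec.b, spec.hazard_multiplier)
    records = validate_survival(pd.concat(frames, ignore_index=True))
    return records, truth


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------

def condition_label(treatment: str, age_days: int) -> str:
    return f"{treatment}_d{age_days}"


def generate_ct(true_rq: Mapping[str, float], ct_noise_sd: float = 0.0,
                seed: int = 0, n_replicates: int = 3,
                reference_ct: float = 20.0, dct_calibrator: float = 2.0,
                target_gene: str = "target",
                reference_gene: str = "betaTub",
                ) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Generate a Ct table whose ideal (noise-free) RQ equals ``true_rq``.

    ``true_rq`` maps condition labels of the form ``"<treatment>_d<age>"``
    (see :func:`condition_label`) to relative expression; it must include a
    calibrator condition with value 1.  Target Ct is
    ``reference Ct + dct_calibrator - log2(true_rq) + N(0, ct_noise_sd)``;
    the reference well carries its own technical noise of the same sd.
    """
    for cond, rq in true_rq.items():
        if rq <= 0:
            raise ConfigError(f"true_rq for {cond!r} must be > 0")
    rng = np.random.default_rng(seed)
    rows = []
    for cond in sorted(true_rq):
        treatment, age_part = cond.rsplit("_d", 1)
        age = int(age_part)
        for rep in range(1, n_replicates + 1):
            sid = f"{cond}_r{rep}"
            ref_ct = reference_ct + rng.normal(0.0, ct_noise_sd)
            tgt_ct = (ref_ct + dct_calibrator
                      - math.log2(true_rq[cond])
                      + rng.normal(0.0, ct_noise_sd))
            rows.append((sid, reference_gene, "reference", ref_ct,
                         treatment, age, rep))
            rows.append((sid, target_gene, "target", tgt_ct,
                         treatment, age, rep))
    table = validate_ct(pd.DataFrame(
        rows, columns=["sample_id", "gene", "role", "ct", "treatment",
                       "age_days", "replicate"]))
    truth = SyntheticTruth(true_rq=dict(true_rq))
    return table, truth
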