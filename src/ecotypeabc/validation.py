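"""Pseudo-observed dataset (POD) validation of the ABC pipeline.

PODs are full simulations drawn from the inference priors with known
parameters.  Two diagnostics are provided: model-choice confusion rates
(how often the generating model is supported with high posterior
probability against a competitor, using the same reference tables and
retention settings as the real analysis) and posterior-quantile
calibration (under correct inference the posterior CDF evaluated at the
true parameter is uniform on (0, 1) across PODs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import abc_engine
from .abc_engine import PlsTransform, SimulationTable
from .demographic_models import PriorSpec, draw_parameters
from .coalescent_sim import LocusSpec, simulate_dataset
from .sumstats import assemble_vector

__all__ = [
    "PodBatch",
    "generate_pods",
    "classify_pod",
    "confusion_rates",
    "quantile_calibration",
]

logger = logging.getLogger(__name__)


@dataclass
class PodBatch:
    """Pseudo-observed datasets for one model: true parameters paired
    with summary-statistic vectors."""

    model: str
    params: pd.DataFrame
    stats: pd.DataFrame
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.params)


def generate_pods(
    model: str,
    priors: dict[str, PriorSpec],
    n: int,
    rng: np.random.Generator,
    samples_seq: dict[str, int],
    samples_aflp: dict[str, int],
    loci: list[LocusSpec] | None = None,
    n_aflp: int | None = None,
    mode: str = "combined",
) -> PodBatch:
    """Simulate ``n`` independent full datasets from the priors, each
    reduced to its summary-statistic vector with true parameters kept."""
    if n < 1:
        raise ValueError("n must be >= 1")
    from .workbench import _roster_for  # local import to avoid a cycle

    recs, vecs = [], []
    while len(vecs) < n:
        rec = draw_parameters(model, priors, rng)
        ds = simulate_dataset(
            rec, samples_seq, samples_aflp, rng,
            loci=loci if loci is not None else _roster_for(rec, n_aflp),
        )
        vec = assemble_vector(ds, mode=mode)
        if not np.isfinite(vec.to_numpy()).all():
            continue  # sentinel statistics: redraw, as in table building
        recs.append({k: v for k, v in rec.items() if k != "model"})
        vecs.append(vec)
    return PodBatch(model, pd.DataFrame(recs), pd.DataFrame(vecs).reset_index(drop=True))


def classify_pod(
    observed: pd.Series,
    tables: dict[str, SimulationTable],
    transforms: dict[str, PlsTransform],
    priors: dict[str, dict[str, PriorSpec]],
    retain_frac: float,
    rng: np.random.Generator,
    components: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Model comparison for one observed vector: per candidate model,
    PLS rejection with that model's transform, then a GLM on all raw
    statistics to obtain a comparable marginal density."""
    results = {}
    for m, tab in tables.items():
        k = abc_engine.retained_count(len(tab), retain_frac)
        idx, dist = abc_engine.reject(
            observed, tab, transforms[m], k,
            sim_components=components[m] if components else None)
        results[m] = abc_engine.glm_adjust(
            tab, idx, observed, priors[m], transform=None,
            normaliser=transforms[m], rng=rng, distances=dist,
            compute_grids=False,
        )
    return abc_engine.compare_models(results)


def confusion_rates(
    pods: dict[str, PodBatch],
    tables: dict[str, SimulationTable],
    transforms: dict[str, PlsTransform],
    priors: dict[str, dict[str, PriorSpec]],
    retain_frac: float = 0.01,
    threshold: float = 0.95,
    rng: np.random.Generator | None = None,
) -> dict[str, float]:
    """Pooled model-choice confusion fractions over PODs of all models.

    Each POD is assigned to the model whose posterior probability exceeds
    ``threshold``; otherwise it is undecided.  Returns the fractions of
    correct, wrong and undecided assignments (summing to 1) plus the
    per-model decision counts.
    """
    rng = rng or np.random.default_rng()
    if not pods or any(len(b) == 0 for b in pods.values()):
        raise ValueError("empty POD batch")
    components = {m: transforms[m].apply(tables[m].stats) for m in tables}
    n_correct = n_wrong = n_undecided = 0
    per_model: dict[str, dict[str, int]] = {}
    for true_model, batch in pods.items():
        tally = {"correct": 0, "wrong": 0, "undecided": 0}
        for i in range(len(batch)):
            cmp = classify_pod(batch.stats.iloc[i], tables, transforms,
                               priors, retain_frac, rng, components=components)
            best = cmp.loc[cmp["posterior_probability"].idxmax()]
            if best["posterior_probability"] > threshold:
                if best["model"] == true_model:
                    tally["correct"] += 1
                else:
                    tally["wrong"] += 1
            else:
                tally["undecided"] += 1
        per_model[true_model] = tally
        n_correct += tally["correct"]
        n_wrong += tally["wrong"]
        n_undecided += tally["undecided"]
    n_total = n_correct + n_wrong + n_undecided
    return {
        "correct": n_correct / n_total,
        "wrong": n_wrong / n_total,
        "undecided": n_undecided / n_total,
        "n_pods": n_total,
        "per_model": per_model,
    }


def quantile_calibration(
    batch: PodBatch,
    table: SimulationTable,
    transform: PlsTransform,
    priors: dict[str, PriorSpec],
    retain_frac: float = 0.01,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Posterior quantiles of the true parameter values across PODs.

    For each POD and parameter, q = posterior CDF at the truth; exact
    calibration makes q uniform on (0, 1).  Returns per-parameter
    Kolmogorov-Smirnov distance and p-value against uniformity, plus the
    raw quantiles (one column per parameter).
    """
    rng = rng or np.random.default_rng()
    if len(batch) == 0:
        raise ValueError("empty POD batch")
    names = list(priors)
    quantiles = {n: [] for n in names}
    components = transform.apply(table.stats)
    for i in range(len(batch)):
        obs = batch.stats.iloc[i]
        k = abc_engine.retained_count(len(table), retain_frac)
        idx, dist = abc_engine.reject(obs, table, transform, k,
                                      sim_components=components)
        res = abc_engine.glm_adjust(table, idx, obs, priors,
                                    transform=transform, rng=rng)
        for n in names:
            truth = float(batch.params.iloc[i][n])
            quantiles[n].append(res.cdf_at(n, truth))
    rows = []
    for n in names:
        q = np.asarray(quantiles[n])
        degenerate = np.mean((q <= 1e-6) | (q >= 1 - 1e-6))
        if degenerate > 0.5:
            logger.warning("parameter %s: %.0f%% of posteriors put the truth "
                           "at a CDF boundary", n, 100 * degenerate)
        ks = sps.kstest(q, "uniform")
        rows.append({"parameter": n, "ks_distance": ks.statistic,
                     "ks_pvalue": ks.pvalue, "n_pods": len(q)})
    report = pd.DataFrame(rows)
    report.attrs["quantiles"] = pd.DataFrame(quantiles)
    return report
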