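"""Study design, I/O, the end-to-end pipeline, and the command line.

The synthetic observed-dataset generator stands in for the field data:
it simulates the full study design (2 ecotypes x 2 localities; 16
sequences per group for the four sequence loci; 26 diploid individuals
per group for 462 AFLP loci) under one of the demographic models with
known parameters, and writes it in the exchange formats the pipeline
reads back (per-group FASTA for sequence loci, a TSV band matrix for
AFLP, a JSON manifest with provenance).

``run_pipeline`` chains the stages of a real analysis: outlier scan and
filtering, summary statistics, per-model simulation tables, PLS fitting,
rejection, GLM adjustment, model comparison, and optional POD
validation.  Every stage logs its seeds and settings.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import click
import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import abc_engine, outlier_scan, scar_stats, validation
from .abc_engine import SimulationTable
from .coalescent_sim import LocusSpec, MultiMarkerDataset, default_locus_roster, simulate_dataset
from .demographic_models import MODELS, PriorSpec, default_priors, draw_parameters
from .sumstats import assemble_vector

__all__ = [
    "StudyDesign",
    "make_synthetic_observed",
    "read_dataset",
    "write_dataset",
    "simulate_table",
    "run_pipeline",
    "cli",
]

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))
_BASE_CODE = {b: i for i, b in enumerate("ACGT")}

# Retention fractions mirror the study's counts out of 1e6 simulations:
# 10,000 (1%) for combined statistics, 20,000 (2%) for AFLP only,
# 5,000 (0.5%) for sequence only.
RETAIN_FRACTIONS = {"combined": 0.01, "aflp": 0.02, "sequence": 0.005}


@dataclass(frozen=True)
class StudyDesign:
    """Sampling configuration: 2 ecotypes x 2 localities throughout."""

    seq_per_group: int = 16  # sequences per group, all four sequence loci
    aflp_per_group: int = 26  # diploid individuals per group
    n_aflp: int = 462  # simulated AFLP loci
    n_localities: int = 2
    n_ecotypes: int = 2

    def __post_init__(self):
        if min(self.seq_per_group, self.aflp_per_group, self.n_aflp) < 1:
            raise ValueError("design sizes must be positive")
        if (self.n_localities, self.n_ecotypes) != (2, 2):
            raise ValueError("the pipeline supports exactly 2 localities x 2 ecotypes")

    @classmethod
    def scaled(cls) -> "StudyDesign":
        """Desk-scale design for simulation-heavy validation runs:
        identical structure, smaller samples (8 sequences and 8 diploid
        individuals per group, 50 AFLP loci)."""
        return cls(seq_per_group=8, aflp_per_group=8, n_aflp=50)

    def groups(self, model: str) -> tuple[str, ...]:
        unit = "loc" if model.endswith("_within") else "region"
        return tuple(f"{unit}{i}-{e}" for i in (1, 2) for e in ("crab", "wave"))

    def samples_seq(self, model: str) -> dict[str, int]:
        return {g: self.seq_per_group for g in self.groups(model)}

    def samples_aflp(self, model: str) -> dict[str, int]:
        return {g: self.aflp_per_group for g in self.groups(model)}


def _roster_for(rec: dict, n_aflp: int | None = None) -> list[LocusSpec]:
    return default_locus_roster(rec["MU"], rec["AFLPMU"], n_aflp or 462)


# ---------------------------------------------------------------------------
# dataset I/O
# ---------------------------------------------------------------------------

def write_dataset(dataset: MultiMarkerDataset, outdir: str | Path) -> Path:
    """Write per-group FASTA files, the AFLP TSV and a JSON manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for locus, by_group in dataset.sequences.items():
        for group, aln in by_group.items():
            recs = [
                SeqRecord(Seq("".join(_BASES[row])), id=f"{group}_{i}", description="")
                for i, row in enumerate(aln)
            ]
            SeqIO.write(recs, out / f"{locus}.{group}.fasta", "fasta")
    aflp = pd.DataFrame(dataset.aflp, columns=list(dataset.aflp_locus_names))
    aflp.insert(0, "group", dataset.aflp_groups)
    aflp.insert(0, "individual", [f"ind{i:03d}" for i in range(len(aflp))])
    aflp.to_csv(out / "aflp.tsv", sep="\t", index=False)
    manifest = {
        "groups": list(dataset.groups),
        "sequence_loci": {
            locus: next(iter(by.values())).shape[1]
            for locus, by in dataset.sequences.items()
        },
        "n_aflp": int(dataset.aflp.shape[1]),
        "provenance": dataset.provenance,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))
    return out


def read_dataset(indir: str | Path) -> MultiMarkerDataset:
    """Read a dataset written by :func:`write_dataset` (or assembled by
    hand in the same formats)."""
    indir = Path(indir)
    manifest = json.loads((indir / "manifest.json").read_text())
    groups = tuple(manifest["groups"])
    sequences: dict[str, dict[str, np.ndarray]] = {}
    for locus in manifest["sequence_loci"]:
        by = {}
        for group in groups:
            recs = list(SeqIO.parse(indir / f"{locus}.{group}.fasta", "fasta"))
            by[group] = np.array(
                [[_BASE_CODE[b] for b in str(r.seq).upper()] for r in recs],
                dtype=np.int8,
            )
        sequences[locus] = by
    aflp_df = pd.read_csv(indir / "aflp.tsv", sep="\t")
    locus_cols = [c for c in aflp_df.columns if c not in ("individual", "group")]
    return MultiMarkerDataset(
        groups=groups,
        sequences=sequences,
        aflp=aflp_df[locus_cols].to_numpy(dtype=np.int8),
        aflp_groups=aflp_df["group"].to_numpy(),
        aflp_locus_names=tuple(locus_cols),
        provenance=manifest.get("provenance", {}),
    )


def make_synthetic_observed(
    design: StudyDesign,
    model: str,
    true_params: dict | None = None,
    seed: int = 0,
    outdir: str | Path | None = None,
    priors: dict[str, PriorSpec] | None = None,
) -> tuple[MultiMarkerDataset, dict]:
    """Simulate a synthetic observed dataset under ``model``.

    ``true_params`` fixes the generating parameter record (drawn from the
    priors when omitted); the dataset, with its provenance manifest, is
    written to ``outdir`` when given.
    """
    rng = np.random.default_rng(seed)
    rec = dict(true_params) if true_params else draw_parameters(
        model, priors or default_priors(model), rng)
    rec.setdefault("model", model)
    ds = simulate_dataset(
        rec, design.samples_seq(model), design.samples_aflp(model), rng,
        loci=_roster_for(rec, design.n_aflp),
    )
    ds.provenance.update({"model": model, "seed": seed, "design": asdict(design)})
    if outdir is not None:
        write_dataset(ds, outdir)
    return ds, rec


# ---------------------------------------------------------------------------
# simulation tables
# ---------------------------------------------------------------------------

def simulate_table(
    model: str,
    priors: dict[str, PriorSpec],
    n_sims: int,
    design: StudyDesign,
    rng: np.random.Generator,
    mode: str = "combined",
    n_aflp: int | None = None,
) -> SimulationTable:
    """Draw ``n_sims`` parameter records, simulate each dataset, and
    collect the summary-statistic vectors; rows with sentinel (NaN)
    statistics are dropped."""
    s_seq = design.samples_seq(model)
    s_aflp = design.samples_aflp(model)
    n_loci = n_aflp if n_aflp is not None else design.n_aflp
    recs, vecs = [], []
    for _ in range(n_sims):
        rec = draw_parameters(model, priors, rng)
        ds = simulate_dataset(rec, s_seq, s_aflp, rng, loci=_roster_for(rec, n_loci))
        recs.append({k: v for k, v in rec.items() if k != "model"})
        vecs.append(assemble_vector(ds, mode=mode))
    table = SimulationTable(pd.DataFrame(recs), pd.DataFrame(vecs).reset_index(drop=True), model)
    filtered = table.drop_sentinels()
    if len(filtered) < len(table):
        logger.info("dropped %d/%d simulations with sentinel statistics",
                    len(table) - len(filtered), len(table))
    return filtered


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

_REQUIRED_CONFIG = ("seed", "models", "n_sims")


def _check_config(config: dict) -> None:
    for key in _REQUIRED_CONFIG:
        if key not in config:
            raise ValueError(f"missing config key: {key!r}")
    for m in config["models"]:
        if m not in MODELS:
            raise ValueError(f"unknown model {m!r} in config")


def _design_from_config(config: dict) -> StudyDesign:
    d = config.get("design", {})
    if d == "scaled":
        return StudyDesign.scaled()
    return StudyDesign(**d) if d else StudyDesign()


def _priors_from_config(config: dict, model: str) -> dict[str, PriorSpec]:
    priors = default_priors(model)
    for name, spec in config.get("priors", {}).items():
        if name in priors:
            if isinstance(spec, (int, float)):  # fixed value: degenerate prior
                eps = abs(spec) * 1e-9 + 1e-12
                priors[name] = PriorSpec(name, "uniform", spec - eps, spec + eps)
            else:
                priors[name] = PriorSpec(name, spec.get("kind", priors[name].kind),
                                         float(spec["lower"]), float(spec["upper"]))
    return priors


def run_pipeline(config: dict) -> dict:
    """Run the full analysis described by a config mapping.

    Required keys: ``seed``, ``models`` (list of model names), ``n_sims``
    (simulations per model).  Optional: ``design`` (mapping or
    "scaled"), ``observed`` (directory of an observed dataset; a
    synthetic one is generated under ``synthetic_model`` otherwise),
    ``mode`` (combined/sequence/aflp), ``retain_frac``, ``pls_components``,
    ``outlier_scan`` (bool, default True), ``validation``
    ({"n_pods": ...}), ``outdir``, ``priors`` overrides.
    """
    _check_config(config)
    seed = int(config["seed"])
    rng = np.random.default_rng(seed)
    design = _design_from_config(config)
    mode = config.get("mode", "combined")
    retain_frac = float(config.get("retain_frac", RETAIN_FRACTIONS[mode]))
    outdir = Path(config.get("outdir", "ecotypeabc_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    logger.info("pipeline seed=%d design=%s mode=%s retain=%.4f",
                seed, design, mode, retain_frac)

    # --- observed data ------------------------------------------------
    if "observed" in config:
        observed = read_dataset(config["observed"])
        truth = None
    else:
        model0 = config.get("synthetic_model", config["models"][0])
        observed, truth = make_synthetic_observed(
            design, model0, config.get("synthetic_params"),
            seed=int(rng.integers(2**31 - 1)),
        )
        logger.info("generated synthetic observed data under %s", model0)

    # --- outlier scan & filter ---------------------------------------
    scan_reports = {}
    if config.get("outlier_scan", True) and observed.aflp.size:
        drop = np.zeros(observed.aflp.shape[1], dtype=bool)
        groups = observed.groups
        pairs = [(groups[0], groups[1]), (groups[2], groups[3])]
        for ga, gb in pairs:
            a = observed.aflp[observed.aflp_groups == ga]
            b = observed.aflp[observed.aflp_groups == gb]
            rep = outlier_scan.scan_pair(a, b, rng,
                                         n_loci_sim=int(config.get("n_null_loci", 5000)))
            scan_reports[f"{ga}|{gb}"] = rep
            drop |= rep.per_locus["outlier"].to_numpy()
            rep.per_locus.to_csv(outdir / f"outliers.{ga}_{gb}.tsv", sep="\t", index=False)
        if drop.any():
            logger.info("removing %d outlier loci before inference", int(drop.sum()))
            observed.aflp = observed.aflp[:, ~drop]
            observed.aflp_locus_names = tuple(
                n for n, d in zip(observed.aflp_locus_names, drop) if not d)

    n_aflp_clean = observed.aflp.shape[1]
    obs_vec = assemble_vector(observed, mode=mode)
    obs_vec.to_frame().T.to_csv(outdir / "observed_stats.tsv", sep="\t", index=False)

    # --- per-model simulation, PLS, rejection, GLM --------------------
    tables, transforms, model_priors, estimates, results = {}, {}, {}, {}, {}
    for model in config["models"]:
        priors = _priors_from_config(config, model)
        model_priors[model] = priors
        logger.info("simulating %d datasets under %s", config["n_sims"], model)
        tab = simulate_table(model, priors, int(config["n_sims"]), design, rng,
                             mode=mode, n_aflp=n_aflp_clean)
        tab.save(str(outdir / f"table.{model}"))
        tr = abc_engine.fit_pls(tab, priors, config.get("pls_components"), rng=rng)
        tables[model], transforms[model] = tab, tr
        k = abc_engine.retained_count(len(tab), retain_frac)
        idx, dist = abc_engine.reject(obs_vec, tab, tr, k)
        # parameter estimation in PLS space
        est = abc_engine.glm_adjust(tab, idx, obs_vec, priors, transform=tr,
                                    rng=rng, distances=dist)
        estimates[model] = est
        abc_engine.posterior_summaries(est).to_csv(
            outdir / f"posterior.{model}.tsv", sep="\t", index=False)
        # model comparison on the full (Box-Cox-normalised) statistic set
        results[model] = abc_engine.glm_adjust(tab, idx, obs_vec, priors,
                                               transform=None, normaliser=tr,
                                               rng=rng, compute_grids=False)

    comparison = abc_engine.compare_models(results) if len(results) > 1 else None
    if comparison is not None:
        comparison.to_csv(outdir / "model_comparison.tsv", sep="\t", index=False)

    # --- optional POD validation --------------------------------------
    confusion = None
    if config.get("validation"):
        n_pods = int(config["validation"].get("n_pods", 100))
        pods = {
            m: validation.generate_pods(
                m, model_priors[m], n_pods, rng,
                design.samples_seq(m), design.samples_aflp(m),
                n_aflp=n_aflp_clean, mode=mode)
            for m in config["models"]
        }
        confusion = validation.confusion_rates(
            pods, tables, transforms, model_priors,
            retain_frac=retain_frac, rng=rng)
        pd.DataFrame([{k: v for k, v in confusion.items() if k != "per_model"}]).to_csv(
            outdir / "confusion.tsv", sep="\t", index=False)

    report = {
        "seed": seed,
        "design": asdict(design),
        "mode": mode,
        "observed_truth": truth,
        "n_aflp_after_filter": n_aflp_clean,
        "scan_reports": scan_reports,
        "comparison": comparison,
        "estimates": estimates,
        "posterior_summaries": {m: abc_engine.posterior_summaries(e)
                                for m, e in estimates.items()},
        "confusion": confusion,
        "outdir": outdir,
    }
    return report


# ---------------------------------------------------------------------------
# command line
# ---------------------------------------------------------------------------

def _load_config(path: str) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


@click.group()
@click.option("-v", "--verbose", is_flag=True, help="log at INFO level")
def cli(verbose):
    """ABC model choice for the origin of ecotype pairs."""
    logging.basicConfig(
        level=logging.INFO if verbose else logging.WARNING,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )


@cli.command()
@click.option("--model", type=click.Choice(MODELS), default="parallel_within")
@click.option("--seed", type=int, default=0)
@click.option("--scaled", is_flag=True, help="use the desk-scale design")
@click.option("--out", type=click.Path(), required=True)
def synth(model, seed, scaled, out):
    """Generate a synthetic observed dataset."""
    design = StudyDesign.scaled() if scaled else StudyDesign()
    _, rec = make_synthetic_observed(design, model, seed=seed, outdir=out)
    click.echo(f"wrote {out} (model={model}, seed={seed})")


@cli.command()
@click.option("--data", type=click.Path(exists=True), required=True)
@click.option("--seed", type=int, default=0)
@click.option("--out", type=click.Path(), required=True)
def scan(data, seed, out):
    """Outlier-scan the AFLP matrix of a dataset directory."""
    ds = read_dataset(data)
    rng = np.random.default_rng(seed)
    g = ds.groups
    frames = []
    for ga, gb in [(g[0], g[1]), (g[2], g[3])]:
        rep = outlier_scan.scan_pair(ds.aflp[ds.aflp_groups == ga],
                                     ds.aflp[ds.aflp_groups == gb], rng)
        f = rep.per_locus.copy()
        f.insert(0, "pair", f"{ga}|{gb}")
        frames.append(f)
    pd.concat(frames).to_csv(out, sep="\t", index=False)
    click.echo(f"wrote {out}")


@cli.command()
@click.option("--data", type=click.Path(exists=True), required=True)
@click.option("--mode", type=click.Choice(["combined", "sequence", "aflp"]),
              default="combined")
@click.option("--out", type=click.Path(), required=True)
def stats(data, mode, out):
    """Summary-statistic vector of a dataset directory."""
    vec = assemble_vector(read_dataset(data), mode=mode)
    vec.to_frame().T.to_csv(out, sep="\t", index=False)
    click.echo(f"wrote {out} ({len(vec)} statistics)")


@cli.command()
@click.option("--config", "config_path", type=click.Path(exists=True), required=True)
@click.option("--model", type=click.Choice(MODELS), required=True)
@click.option("--out", type=click.Path(), required=True)
def simulate(config_path, model, out):
    """Simulate a parameter/statistic table for one model."""
    config = _load_config(config_path)
    _check_config(config)
    design = _design_from_config(config)
    rng = np.random.default_rng(int(config["seed"]))
    tab = simulate_table(model, _priors_from_config(config, model),
                         int(config["n_sims"]), design, rng,
                         mode=config.get("mode", "combined"))
    tab.save(out)
    click.echo(f"wrote {out}.params.tsv / {out}.stats.tsv ({len(tab)} rows)")


@cli.command()
@click.option("--config", "config_path", type=click.Path(exists=True), required=True)
def fit(config_path):
    """Run the full pipeline (scan, stats, simulate, reject, GLM, compare)."""
    report = run_pipeline(_load_config(config_path))
    if report["comparison"] is not None:
        click.echo(report["comparison"].to_string(index=False))
    for model, summ in report["posterior_summaries"].items():
        click.echo(f"\n[{model}]")
        click.echo(summ.to_string(index=False))


@cli.command()
@click.option("--config", "config_path", type=click.Path(exists=True), required=True)
def compare(config_path):
    """Model comparison only (alias for fit; prints the comparison table)."""
    report = run_pipeline(_load_config(config_path))
    if report["comparison"] is None:
        raise click.ClickException("config must list >= 2 models")
    click.echo(report["comparison"].to_string(index=False))


@cli.command()
@click.option("--config", "config_path", type=click.Path(exists=True), required=True)
def validate(config_path):
    """POD validation: confusion rates for the configured models."""
    config = _load_config(config_path)
    config.setdefault("validation", {"n_pods": 50})
    report = run_pipeline(config)
    conf = report["confusion"]
    click.echo(f"correct={conf['correct']:.3f} wrong={conf['wrong']:.3f} "
               f"undecided={conf['undecided']:.3f} (n={conf['n_pods']})")


@cli.command("scar-test")
@click.option("--counts", type=click.Path(exists=True), default=None,
              help="TSV of region/locality/morph/scarred/unscarred "
                   "(bundled table when omitted)")
@click.option("--out", type=click.Path(), default=None)
def scar_test(counts, out):
    """Williams-corrected G decomposition of scar frequencies."""
    table = scar_stats.load_scar_table(counts)
    dec = scar_stats.g_decomposition(table)
    if out:
        dec.to_csv(out, sep="\t", index=False)
    click.echo(dec.to_string(index=False))


if __name__ == "__main__":
    cli()
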