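"""End-to-end orchestration, natural-unit conversions, and reporting.

Time in the inference modules is mutation-scaled; this module converts to
years and effective sizes: years = (height / mu) * generation_time and
N_e = theta / (4 mu).  Defaults are mu = 5e-4 mutations per locus per
generation and a 5-year generation time, with a documented 1e-4 alternative
rate that scales times and sizes by exactly five.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bottleneck import (BOTTLENECK_TPM, M_RATIO_TPM, het_excess_test,
                         m_ratio_test, mode_shift)
from .coalescent import kibale_preset
from .genotypes import GenotypeMatrix, read_csv, read_genepop, screen_null_alleles
from .mutation import MutationModel
from .skyline import (ChainConfig, PriorConfig, compare_models, estimate_lnml,
                      run_mcmc, summarize_posterior)
from .sumstats import delta_mu2_nj, locus_summaries, rst_screen

logger = logging.getLogger(__name__)

ALL_STAGES = ("qc", "sumstats", "structure", "bottleneck", "infer", "compare")


# -- unit conversions --------------------------------------------------------


def transform_log10_summaries(
    mean: float, hpd: tuple[float, float]
) -> tuple[float, float, float]:
    """Back-transform log10-scale posterior summaries to the linear scale."""
    lo, hi = hpd
    out = (10.0 ** mean, 10.0 ** lo, 10.0 ** hi)
    if not all(np.isfinite(out)):
        raise ValueError("non-finite back-transform")
    return out


def scale_to_natural_units(
    height: float,
    theta: float,
    mu: float = 5e-4,
    generation_time: float = 5.0,
) -> tuple[float, float]:
    """(years, N_e) from a mutation-scaled tree height and theta.

    years = (height / mu) * generation_time; N_e = theta / (4 mu).  Halving
    mu doubles both outputs (they scale as 1/mu).
    """
    if height < 0 or theta <= 0 or mu <= 0 or generation_time <= 0:
        raise ValueError("all inputs must be positive")
    return (height / mu) * generation_time, theta / (4.0 * mu)


def generations_to_years(gens: float, generation_time: float) -> float:
    """Convert a number of generations to years."""
    if gens < 0:
        raise ValueError("generations must be >= 0")
    return gens * generation_time


def model_probabilities(lnmls: dict[str, float]) -> dict[str, float]:
    """Relative model probabilities: max-shifted softmax of ln mL values."""
    if not lnmls:
        raise ValueError("need at least one model")
    names = list(lnmls)
    vals = np.array([float(lnmls[n]) for n in names])
    vals = vals - vals.max()
    w = np.exp(vals)
    w = w / w.sum()
    return dict(zip(names, (float(x) for x in w)))


def ne_nc_ratio(ne: float, nc: float) -> float:
    """Effective-to-census population size ratio."""
    if nc <= 0:
        raise ValueError("census size must be > 0")
    return ne / nc


# -- configuration -----------------------------------------------------------


@dataclass
class RunConfig:
    """Pipeline run configuration.

    Either ``input_path``/``input_format`` point at a genotype file, or
    ``simulate=True`` generates the default synthetic dataset.  ``models``
    lists mutation-model names for the inference stage; chain settings are
    shared across models.
    """

    input_path: str | None = None
    input_format: str = "genepop"  # or "csv"
    simulate: bool = False
    sim_theta: float = 2.0
    sim_migration: float = 50.0
    mu: float = 5e-4
    mu_alternative: float = 1e-4
    generation_time: float = 5.0
    census_size: float | None = None
    stages: tuple[str, ...] = ALL_STAGES
    seed: int = 1
    models: tuple[str, ...] = ("PU2", "EU1")
    dem_kind: str = "SKYLINE"
    n_iter: int = 4000
    burn_in: float = 0.10
    thin: int = 5
    m_ratio_theta: float = 5.0
    n_sim_bottleneck: int = 500
    n_perm: int = 1000

    def __post_init__(self) -> None:
        if self.mu <= 0 or self.generation_time <= 0:
            raise ValueError("mu and generation_time must be > 0")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        if "models" in raw:
            raw["models"] = tuple(raw["models"])
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class Report:
    """Stage outputs plus provenance; serializable to Markdown and JSON."""

    sections: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        def conv(obj):
            if isinstance(obj, pd.DataFrame):
                return json.loads(obj.to_json(orient="split"))
            if isinstance(obj, pd.Series):
                return obj.to_dict()
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, dict):
                return {str(k): conv(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [conv(v) for v in obj]
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            return obj

        return {"sections": conv(self.sections), "provenance": self.provenance}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=2, default=str)

    def to_markdown(self) -> str:
        lines = ["# msatdemog pipeline report", ""]
        for name, content in self.sections.items():
            lines.append(f"## {name}")
            if isinstance(content, pd.DataFrame):
                lines.append(content.round(4).to_markdown())
            elif isinstance(content, dict) and content.get("skipped"):
                lines.append("_skipped_")
            else:
                lines.append("```json")
                lines.append(json.dumps(Report(sections={"x": content})
                                        .to_json_dict()["sections"]["x"],
                                        indent=2, default=str))
                lines.append("```")
            lines.append("")
        lines.append("## provenance")
        lines.append("```json")
        lines.append(json.dumps(self.provenance, indent=2))
        lines.append("```")
        return "\n".join(lines)


def _load_input(cfg: RunConfig, rng: np.random.Generator) -> GenotypeMatrix:
    if cfg.simulate:
        return kibale_preset(rng, theta=cfg.sim_theta, migration=cfg.sim_migration)
    if cfg.input_path is None:
        raise ValueError("config must give input_path or set simulate: true")
    if cfg.input_format == "genepop":
        return read_genepop(cfg.input_path)
    if cfg.input_format == "csv":
        return read_csv(cfg.input_path)
    raise ValueError(f"unknown input format {cfg.input_format!r}")


def run_pipeline(cfg: RunConfig) -> Report:
    """Execute the configured stages in order and assemble the report.

    Stage order: QC -> summary statistics -> structure screen -> bottleneck
    tests -> per-model MCMC -> model comparison -> unit conversions.  A
    failing optional stage is logged and marked failed; later stages still
    run.
    """
    rng = np.random.default_rng(cfg.seed)
    report = Report()
    report.provenance = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "version": __version__,
        "mu": cfg.mu,
        "generation_time": cfg.generation_time,
    }
    g = _load_input(cfg, rng)
    report.sections["input"] = {
        "n_individuals": g.n_individuals,
        "n_loci": g.n_loci,
        "groups": {name: g.groups.count(name) for name in g.group_names},
    }

    if "qc" in cfg.stages:
        qc = screen_null_alleles(g, n_perm=cfg.n_perm, rng=rng)
        report.sections["qc"] = qc.to_frame()
        if qc.excluded:
            logger.info("excluding loci: %s", qc.excluded)
            g = qc.apply(g)
    else:
        report.sections["qc"] = {"skipped": True}

    if "sumstats" in cfg.stages:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = locus_summaries(g, n_perm=cfg.n_perm, rng=rng)
        report.sections["sumstats"] = table
    else:
        report.sections["sumstats"] = {"skipped": True}

    if "structure" in cfg.stages:
        try:
            screen = rst_screen(g, n_perm=cfg.n_perm, rng=rng)
            d, newick, split = delta_mu2_nj(g)
            report.sections["structure"] = {
                "rst_overall": screen.rst_overall,
                "p_overall": screen.p_overall,
                "four_nm": screen.four_nm,
                "pairwise_rst": screen.pairwise_rst,
                "delta_mu2": d,
                "nj_newick": newick,
                "deepest_split": split,
            }
        except ValueError as exc:
            logger.warning("structure stage failed: %s", exc)
            report.sections["structure"] = {"failed": str(exc)}
    else:
        report.sections["structure"] = {"skipped": True}

    if "bottleneck" in cfg.stages:
        try:
            het = het_excess_test(g, BOTTLENECK_TPM,
                                  n_sim=cfg.n_sim_bottleneck, rng=rng)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mrt = m_ratio_test(g, theta=cfg.m_ratio_theta,
                                   params=M_RATIO_TPM,
                                   n_sim=cfg.n_sim_bottleneck, rng=rng)
            report.sections["bottleneck"] = {
                "wilcoxon_p": het.wilcoxon_p,
                "dh": het.dh,
                "mode_shift": mode_shift(g),
                "m_mean": mrt.m_mean,
                "m_p": mrt.m_p,
                "m_per_locus": mrt.m_per_locus,
            }
        except ValueError as exc:
            logger.warning("bottleneck stage failed: %s", exc)
            report.sections["bottleneck"] = {"failed": str(exc)}
    else:
        report.sections["bottleneck"] = {"skipped": True}

    posteriors = {}
    if "infer" in cfg.stages:
        lnmls = {}
        infer_out = {}
        for i, name in enumerate(cfg.models):
            model = MutationModel.from_name(
                name,
                i_min=min(l.repeat_min for l in g.loci),
                i_max=max(l.repeat_max for l in g.loci),
            )
            chain = ChainConfig(n_iter=cfg.n_iter, burn_in=cfg.burn_in,
                                thin=cfg.thin, seed=cfg.seed + 97 * (i + 1))
            post = run_mcmc(g, model, dem_kind=cfg.dem_kind,
                            priors=PriorConfig(), chain=chain)
            posteriors[name] = post
            lnml, err = estimate_lnml(post)
            lnmls[name] = (lnml, err)
            summ = summarize_posterior(post)
            tcoal_years, ne = scale_to_natural_units(
                summ.t_coal_mean, float(np.mean([th[0] for th in post.thetas])),
                mu=cfg.mu, generation_time=cfg.generation_time)
            infer_out[name] = {
                "ln_ml": lnml, "ln_ml_error": err,
                "t_coal_mean": summ.t_coal_mean,
                "t_coal_hpd": summ.t_coal_hpd,
                "psi_pmf": summ.psi_pmf,
                "t_coal_years": round(tcoal_years),
                "ne": ne,
            }
        report.sections["infer"] = infer_out
    else:
        report.sections["infer"] = {"skipped": True}

    if "compare" in cfg.stages and len(posteriors) >= 2:
        comp = compare_models({k: v for k, v in
                               ((n, report.sections["infer"][n]["ln_ml"])
                                for n in posteriors)})
        probs = model_probabilities(
            {n: report.sections["infer"][n]["ln_ml"] for n in posteriors})
        report.sections["compare"] = {
            "table": comp.table, "probabilities": probs, "best": comp.best,
        }
    else:
        report.sections["compare"] = {"skipped": True}

    # conversions stage always runs: it is pure arithmetic on stage outputs
    conv = {}
    if posteriors:
        best = max(posteriors,
                   key=lambda n: report.sections["infer"][n]["ln_ml"])
        summ = report.sections["infer"][best]
        for mu, label in ((cfg.mu, "mu_default"), (cfg.mu_alternative, "mu_alt")):
            years, _ = scale_to_natural_units(summ["t_coal_mean"], 1.0, mu=mu,
                                              generation_time=cfg.generation_time)
            conv[label] = {"mu": mu, "t_coal_years": round(years)}
        if cfg.census_size:
            conv["ne_nc"] = ne_nc_ratio(summ["ne"], cfg.census_size)
    report.sections["conversions"] = conv
    return report
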