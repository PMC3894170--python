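"""End-to-end pipeline: simulate -> diversity -> tree -> site patterns -> fit.

A :class:`RunConfig` fully determines a run: every stochastic stage
receives an explicit seed derived from the run seed, and all effective
parameters are recorded in a ``manifest.json`` next to the outputs, so
identical configs produce identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__
from .calibration import (
    CalibrationParams,
    fold_reduction,
    genomewide_rate,
    rate_sensitivity,
)
from .demography import DemographicModel, bundled_model, load_model
from .divergence import distance_matrix, nj_tree, window_bootstrap_support
from .diversity import classify_variant_sites, windowed_heterozygosity
from .errors import CanidPopgenError, ConfigError, StageError
from .io import write_bed, write_phylip, write_site_table, write_vcf
from .loci import LocusSet
from .simulate import simulate_dataset
from .site_patterns import (
    dstat_results_table,
    enumerate_quartets,
    model_fit_error,
    pattern_frequency_table,
)

logger = logging.getLogger("canid_popgen")

DEFAULT_DOGS = ["BOX", "BSJ", "DNG"]
DEFAULT_WOLVES = ["CRW", "CHW", "ISW"]
DEFAULT_OUTGROUP = "GLJ"


@dataclass
class RunConfig:
    """Configuration for a full pipeline run."""

    model: str = "fig5a"  # bundled model name or a YAML path
    seed: int = 1
    n_loci: int = 500
    locus_length: int = 1000
    window_loci: int = 10  # loci per bootstrap window
    block_loci: int = 25  # loci per jackknife block
    bootstrap_reps: int = 100
    het_window_bp: int = 100_000
    flag_threshold: float = 0.015
    fit_models: tuple[str, ...] = ("fig5a", "regional", "isw_source")
    dogs: list[str] = field(default_factory=lambda: list(DEFAULT_DOGS))
    wolves: list[str] = field(default_factory=lambda: list(DEFAULT_WOLVES))
    outgroup: str = DEFAULT_OUTGROUP
    outdir: str = "canid_run"

    def load_model(self) -> DemographicModel:
        if Path(self.model).suffix in {".yaml", ".yml"}:
            if not Path(self.model).exists():
                raise ConfigError(f"model file {self.model!r} does not exist")
            return load_model(self.model)
        try:
            return bundled_model(self.model)
        except FileNotFoundError:
            raise ConfigError(
                f"model {self.model!r} is neither a YAML file nor a bundled model"
            ) from None


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest dict (also written to disk)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "canid-popgen",
        "version": __version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "stages": {},
    }

    def stage(name):
        logger.info("stage: %s", name)
        manifest["stages"][name] = {"seed": config.seed}

    try:
        stage("model")
        model = config.load_model()
        model.save(out / "model.yaml")
    except CanidPopgenError as exc:
        raise StageError("model", str(exc)) from exc

    try:
        stage("simulate")
        data = simulate_dataset(
            model, config.n_loci, config.locus_length, seed=config.seed
        )
        write_vcf(data, out / "loci.vcf")
        write_site_table(data, out / "loci.sites.tsv")
    except CanidPopgenError as exc:
        raise StageError("simulate", str(exc)) from exc

    try:
        stage("diversity")
        het_rows = []
        for s in data.samples:
            track = windowed_heterozygosity(data, s, config.het_window_bp)
            write_bed(
                track.windows.assign(chrom=s)[
                    ["chrom", "start", "end", "het", "called", "rate"]
                ],
                out / f"het_{s}.bed",
            )
            het_rows.append({"sample": s, "heterozygosity": track.genome_rate})
        with open(out / "heterozygosity.tsv", "w") as fh:
            fh.write("sample\theterozygosity\n")
            for r in het_rows:
                fh.write(f"{r['sample']}\t{r['heterozygosity']:.6g}\n")
        sharing = classify_variant_sites(data, config.dogs, config.wolves)
        sharing.as_dataframe().to_csv(out / "sharing.tsv", sep="\t")
    except CanidPopgenError as exc:
        raise StageError("diversity", str(exc)) from exc

    try:
        stage("tree")
        dm = distance_matrix(data, mode="conservative",
                             loci_per_window=config.window_loci)
        write_phylip(dm.values, dm.samples, out / "distances.phy")
        tree = window_bootstrap_support(dm, n_reps=config.bootstrap_reps,
                                        seed=config.seed)
        (out / "tree.nwk").write_text(tree.newick() + "\n")
    except CanidPopgenError as exc:
        raise StageError("tree", str(exc)) from exc

    try:
        stage("site_patterns")
        labels = {s: "dog" for s in config.dogs}
        labels.update({s: "wolf" for s in config.wolves})
        quartets = enumerate_quartets(
            config.dogs + config.wolves, config.outgroup,
            mode="dog_wolf_test", labels=labels,
        )
        table = dstat_results_table(data, quartets, block_loci=config.block_loci)
        table.to_csv(out / "dstat.tsv", sep="\t")
    except CanidPopgenError as exc:
        raise StageError("site_patterns", str(exc)) from exc

    try:
        stage("model_fit")
        all_quartets = enumerate_quartets(
            config.dogs + config.wolves, config.outgroup, mode="all"
        )
        observed = pattern_frequency_table(data, all_quartets,
                                           block_loci=config.block_loci)
        scores = {}
        for name in config.fit_models:
            alt = bundled_model(name) if not Path(name).suffix else load_model(name)
            sim = simulate_dataset(
                alt, config.n_loci, config.locus_length, seed=config.seed + 1
            )
            simulated = pattern_frequency_table(sim, all_quartets,
                                                block_loci=config.block_loci)
            score, flags = model_fit_error(observed, simulated,
                                           config.flag_threshold)
            scores[name] = {"score": score, "n_flags": len(flags)}
        with open(out / "model_fit.json", "w") as fh:
            json.dump(scores, fh, indent=2, sort_keys=True)
        manifest["stages"]["model_fit"]["scores"] = scores
    except CanidPopgenError as exc:
        raise StageError("model_fit", str(exc)) from exc

    try:
        stage("calibration")
        params = CalibrationParams(mu_filtered=model.mutation_rate,
                                   gen_time=model.generation_time)
        ne = {
            name: p.ne
            for name, p in model.populations.items()
            if not isinstance(p.ne, (list, tuple)) and not hasattr(p.ne, "ne_values")
        }
        report = {
            "mu_filtered": params.mu_filtered,
            "gen_time": params.gen_time,
            "mu_genomewide": genomewide_rate(params.mu_filtered,
                                             params.cpg_fraction),
            "divergence_time_ky_sensitivity": rate_sensitivity(
                (0.46e-4, 0.53e-4), (0.66e-8, 1.8e-8),
                params.cpg_fraction, params.gen_time,
            ),
        }
        if "ancDW" in ne and "ancDOG" in ne:
            report["dog_fold_reduction"] = fold_reduction(
                ne["ancDW"], ne["ancDOG"], one_decimal=True
            )
        if "ancDW" in ne and "ancWLF" in ne:
            report["wolf_fold_reduction"] = fold_reduction(
                ne["ancDW"], ne["ancWLF"], one_decimal=True
            )
        with open(out / "calibration.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    except CanidPopgenError as exc:
        raise StageError("calibration", str(exc)) from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
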