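"""Config-driven end-to-end runs: simulate -> build -> filter -> cluster ->
predict -> report.

Each stochastic stage derives its own seed deterministically from the
master seed and the stage name (CRC32 of the name mixed into a
SeedSequence), so toggling one stage never perturbs another and a rerun
with the same config is byte-identical.
"""

from __future__ import annotations

import logging
import sys
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cluster import (
    Partition,
    adjusted_rand_index,
    cut_tree,
    euclidean_distance_matrix,
    extract_discriminative_pattern,
    high_bmi_cluster,
    jaccard_distance_matrix,
    screen_parameters,
    ward_linkage,
    zscore_normalize,
)
from .errors import DataError
from .io import (
    CohortTable,
    PresenceMatrix,
    build_presence_matrix,
    read_cohort_table,
    read_identifications,
)
from .matrix import filter_proteins, subset_samples, summarize_catalog
from .predict import stability_select
from .simulate import SimConfig, default_sim_config, simulate_cohort, simulate_proteome

log = logging.getLogger("plasmapattern")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    mix = np.random.SeedSequence([master_seed, zlib.crc32(stage.encode())])
    return int(mix.generate_state(1)[0] & 0x7FFFFFFF)


@dataclass
class RunConfig:
    """Everything needed to reproduce a pipeline run."""

    outdir: str = "plasmapattern_run"
    seed: int = 0
    # inputs: either simulate=True, or cohort/matrix (or identification) paths
    simulate: bool = True
    sim_config_path: str | None = None
    cohort_path: str | None = None
    matrix_path: str | None = None
    identifications_path: str | None = None
    # stage toggles
    run_cluster: bool = True
    run_predict: bool = True
    # stage parameters
    k: int = 2
    alpha: float = 0.05
    distance: str = "jaccard"
    ward_dialect: str = "D2"
    exclude_groups: list[str] = field(default_factory=list)
    refilter: bool = True
    iterations: int = 10
    fraction: float = 0.9
    folds: int = 10
    repeats: int = 10

    def to_yaml_str(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**doc)


@dataclass
class RunReport:
    """Key numbers of a finished run plus where the artifacts were written."""

    outdir: Path
    n_samples: int
    n_proteins_total: int
    n_proteins_filtered: int
    screen_selected: list[str]
    ari_clinical: float | None
    ari_proteomic: float | None
    pattern: list[str]
    bmi_mean_in: float | None
    bmi_mean_out: float | None
    bmi_p_value: float | None
    consensus: list[str]
    mae_holdout: float | None
    mae_insample: float | None
    n_predict_samples: int | None


def _load_inputs(config: RunConfig) -> tuple[CohortTable, PresenceMatrix]:
    if config.simulate:
        sim = (
            SimConfig.from_yaml(config.sim_config_path)
            if config.sim_config_path
            else default_sim_config()
        )
        seed = stage_seed(config.seed, "simulate")
        cohort = simulate_cohort(sim, seed=seed)
        matrix, truth = simulate_proteome(cohort, sim, seed=seed)
        log.info("simulated cohort: %d samples, %d proteins (%d informative)",
                 len(cohort), len(matrix.protein_ids), len(truth))
        return cohort, matrix
    if not config.cohort_path:
        raise DataError("cohort_path required when simulate is off")
    cohort = read_cohort_table(config.cohort_path)
    if config.matrix_path:
        matrix = PresenceMatrix.read_tsv(config.matrix_path)
    elif config.identifications_path:
        idmap = read_identifications(config.identifications_path)
        matrix = build_presence_matrix(idmap, cohort.sample_ids)
    else:
        raise DataError("matrix_path or identifications_path required")
    return cohort, matrix


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the enabled stages in order and write all artifacts.

    Outputs under ``config.outdir``: cohort.tsv, matrix.tsv,
    matrix_filtered.tsv, screen.tsv, partition.tsv, merges.tsv,
    pattern.tsv, consensus.tsv, coefficients.tsv, predictions.tsv and
    report.txt (which embeds the config echo).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    lines: list[str] = [
        "plasmapattern run report",
        f"version: {__version__}",
        "",
    ]

    cohort, matrix = _load_inputs(config)
    cohort.write_tsv(outdir / "cohort.tsv")
    matrix.write_tsv(outdir / "matrix.tsv")

    summary = summarize_catalog(matrix, cohort)
    filtered = filter_proteins(matrix)
    filtered.write_tsv(outdir / "matrix_filtered.tsv")
    lines += [
        "[catalog]",
        f"samples: {len(cohort)}",
        f"proteins_total: {summary.n_total}",
        f"proteins_core (in all samples): {summary.n_core}",
        f"proteins_after_filter: {summary.n_after_filter}",
    ]
    for g, c in summary.per_group_union.items():
        lines.append(f"group_union[{g}]: {c}")
    lines.append("")

    ari_clin = ari_prot = None
    pattern_ids: list[str] = []
    screen_selected: list[str] = []
    bmi_in = bmi_out = bmi_p = None
    if config.run_cluster:
        group_part = Partition.from_groups(cohort)
        screen = screen_parameters(cohort, alpha=config.alpha)
        pd.DataFrame(
            [
                {"parameter": r.parameter, "statistic": r.statistic,
                 "p_value": r.p_value, "selected": r.selected}
                for r in screen
            ]
        ).to_csv(outdir / "screen.tsv", sep="\t", index=False)
        selected = [r.parameter for r in screen if r.selected]
        screen_selected = selected
        lines += ["[clinical]", f"screened_parameters: {len(screen)}",
                  f"selected ({config.alpha:g}): {', '.join(selected) or '(none)'}"]
        if selected:
            z = zscore_normalize(cohort.clinical_frame()[selected])
            dend_c = ward_linkage(euclidean_distance_matrix(z), dialect=config.ward_dialect)
            part_c = cut_tree(dend_c, len(set(cohort.groups)))
            ari_clin = adjusted_rand_index(part_c, group_part)
            lines.append(f"ARI clinical clustering vs BMI groups: {ari_clin:.3f}")
        lines.append("")

        dist = (
            jaccard_distance_matrix(filtered)
            if config.distance == "jaccard"
            else euclidean_distance_matrix(filtered.values.astype(float), filtered.sample_ids)
        )
        dend = ward_linkage(dist, dialect=config.ward_dialect)
        pd.DataFrame(dend.merges, columns=["left", "right", "height", "size"]).to_csv(
            outdir / "merges.tsv", sep="\t", index=False
        )
        part = cut_tree(dend, config.k)
        pd.DataFrame({"sample_id": part.ids, "cluster": part.labels}).to_csv(
            outdir / "partition.tsv", sep="\t", index=False
        )
        ari_prot = adjusted_rand_index(part, group_part)
        target = high_bmi_cluster(part, cohort)
        pattern = extract_discriminative_pattern(
            filtered, part, target, alpha=config.alpha, cohort=cohort
        )
        pattern.table.to_csv(outdir / "pattern.tsv", sep="\t", index=False)
        pattern_ids = pattern.pattern
        bmi_in, bmi_out, bmi_p = (
            pattern.bmi_mean_in, pattern.bmi_mean_out, pattern.bmi_p_value
        )
        lines += [
            "[proteomic clustering]",
            f"distance: {config.distance}; ward dialect: {config.ward_dialect}; k: {config.k}",
            f"ARI proteomic clustering vs BMI groups: {ari_prot:.3f}",
            f"high-BMI cluster: {target} "
            f"({len(part.members(target))} samples)",
            f"cluster BMI mean {bmi_in:.1f} vs {bmi_out:.1f} (p = {bmi_p:.3g})",
            f"discriminative pattern ({len(pattern_ids)} proteins): "
            f"{', '.join(pattern_ids) or '(none)'}",
            "",
        ]

    consensus: list[str] = []
    mae_holdout = mae_insample = None
    n_pred = None
    if config.run_predict:
        pm, pc = (filtered, cohort)
        if config.exclude_groups:
            pm, pc = subset_samples(matrix, cohort, set(config.exclude_groups),
                                    refilter=config.refilter)
        n_pred = len(pc)
        result = stability_select(
            pm.values.astype(float),
            pc.bmi,
            iterations=config.iterations,
            fraction=config.fraction,
            folds=config.folds,
            repeats=config.repeats,
            seed=stage_seed(config.seed, "predict"),
            feature_ids=pm.protein_ids,
        )
        consensus = sorted(result.consensus)
        mae_holdout, mae_insample = result.mae_holdout, result.mae_insample
        pd.DataFrame(
            sorted(result.selection_frequency.items(), key=lambda kv: (-kv[1], kv[0])),
            columns=["protein", "selection_frequency"],
        ).to_csv(outdir / "consensus.tsv", sep="\t", index=False)
        pd.DataFrame(
            [{"term": "intercept", "coefficient": result.final_model.intercept}]
            + [
                {"term": p, "coefficient": b}
                for p, b in result.final_model.coefficients.items()
            ]
        ).to_csv(outdir / "coefficients.tsv", sep="\t", index=False)
        preds = result.final_model.predict(
            pm.select_proteins([p for p in pm.protein_ids if p in result.consensus]).values.astype(float)
            if consensus else np.zeros((n_pred, 0)),
            consensus if consensus else [],
        ) if consensus else np.full(n_pred, float(np.mean(pc.bmi)))
        pd.DataFrame(
            {"sample_id": pc.sample_ids, "bmi_true": pc.bmi, "bmi_predicted": preds}
        ).to_csv(outdir / "predictions.tsv", sep="\t", index=False, float_format="%.4f")
        lines += [
            "[prediction]",
            f"samples used: {n_pred}"
            + (f" (excluding {', '.join(config.exclude_groups)})" if config.exclude_groups else ""),
            f"iterations: {config.iterations} x {config.fraction:.0%} subsamples, "
            f"{config.repeats} x {config.folds}-fold CV",
            f"consensus panel ({len(consensus)} proteins): {', '.join(consensus) or '(none)'}",
            f"MAE holdout-pooled: "
            + (f"{mae_holdout:.2f} kg/m^2" if mae_holdout == mae_holdout else "n/a"),
            f"MAE refit-insample: {mae_insample:.2f} kg/m^2",
            "",
        ]

    lines += ["[config]", config.to_yaml_str().rstrip(), ""]
    (outdir / "report.txt").write_text("\n".join(lines))
    log.info("report written to %s", outdir / "report.txt")
    return RunReport(
        outdir=outdir,
        n_samples=len(cohort),
        n_proteins_total=summary.n_total,
        n_proteins_filtered=summary.n_after_filter,
        screen_selected=screen_selected,
        ari_clinical=ari_clin,
        ari_proteomic=ari_prot,
        pattern=pattern_ids,
        bmi_mean_in=bmi_in,
        bmi_mean_out=bmi_out,
        bmi_p_value=bmi_p,
        consensus=consensus,
        mae_holdout=mae_holdout,
        mae_insample=mae_insample,
        n_predict_samples=n_pred,
    )


def configure_logging(verbose: bool = False) -> None:
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(levelname)s %(name)s: %(message)s",
    )
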