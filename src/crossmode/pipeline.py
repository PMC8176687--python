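"""End-to-end pipeline: simulate -> normalize -> DE -> classify -> context.

One config drives every stage; a persisted config plus seed reproduces all
TSV artifacts byte-for-byte.  Stage seeds are derived deterministically
from the top-level seed so stages stay independently reproducible.  All
thresholds default to the source analysis values (CPM 0.5, FDR 0.05,
diff-ratio thresholds 0.8/0.2, 100 kb window) and are echoed in the run
report.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import classify as _classify
from . import de as _de
from . import expression as _expr
from .context import direction_concordance, neighbor_pairs, read_annotation
from .design import make_design, read_design, write_design
from .errors import ConfigError
from .simulate import SimulationConfig, assign_gene_truth, simulate_counts, write_truth

__all__ = ["RunConfig", "run_pipeline", "load_config", "save_config"]


@dataclass
class RunConfig:
    """Serializable pipeline configuration (YAML round-trippable)."""

    out_dir: str = "crossmode_run"
    seed: int = 0
    # stage toggles
    simulate: bool = True
    normalize: bool = True
    de: bool = True
    classify: bool = True
    context: bool = False
    # inputs when not simulating
    counts_path: str | None = None
    design_path: str | None = None
    annotation_path: str | None = None
    # simulation
    sim: dict = field(default_factory=dict)
    # normalization
    cpm_threshold: float = 0.5
    filter_min_samples: int = 3
    prior_count: float = 0.5
    # differential expression
    fdr: float = 0.05
    min_abs_log2fc: float = 0.0
    # classifier
    theta_high: float = 0.8
    theta_low: float = 0.2
    min_d14: float = 0.5
    classifier_mode: str = "consistent"
    # genomic context
    max_neighbor_distance: int = 100_000
    lnc_biotype: str = "lncRNA"

    def validate(self) -> None:
        if self.classify and not self.de:
            raise ConfigError("classify requires the DE stage (purebred DEG set)")
        if self.de and not self.normalize:
            raise ConfigError("DE requires the normalize stage")
        if self.normalize and not self.simulate and not (self.counts_path and self.design_path):
            raise ConfigError("without simulation, counts_path and design_path are required")
        if self.context and not self.annotation_path:
            raise ConfigError("context stage requires annotation_path")

    def simulation_config(self) -> SimulationConfig:
        sim = dict(self.sim)
        sim.setdefault("seed", self.seed)
        return SimulationConfig(**sim)

    def thresholds(self) -> _classify.ClassifierThresholds:
        return _classify.ClassifierThresholds(
            theta_high=self.theta_high,
            theta_low=self.theta_low,
            min_d14=self.min_d14,
            mode=self.classifier_mode,
        )


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig(**data)


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages and return the run report (also written
    to ``out_dir/report.json``).

    Artifacts: counts.tsv, design.csv, truth.tsv (simulated runs),
    per-tissue log-CPM and DE tables, inheritance calls and the tissue x
    category count table.  Every reported count equals the corresponding
    artifact's row count.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "seed": config.seed,
        "thresholds": {
            "cpm_threshold": config.cpm_threshold,
            "filter_min_samples": config.filter_min_samples,
            "prior_count": config.prior_count,
            "fdr": config.fdr,
            "min_abs_log2fc": config.min_abs_log2fc,
            "theta_high": config.theta_high,
            "theta_low": config.theta_low,
            "min_d14": config.min_d14,
            "classifier_mode": config.classifier_mode,
            "max_neighbor_distance": config.max_neighbor_distance,
        },
        "stages": {},
        "artifacts": {},
    }

    def record(name: str, path: Path, rows: int) -> None:
        report["artifacts"][name] = {
            "path": str(path),
            "sha256": _sha256(path),
            "rows": rows,
        }

    truth = None
    if config.simulate:
        sim_cfg = config.simulation_config()
        design = make_design()
        truth = assign_gene_truth(sim_cfg)
        matrix = simulate_counts(design, truth, sim_cfg)
        write_design(design, out / "design.csv")
        write_truth(truth, out / "truth.tsv")
        _expr.write_counts(matrix, out / "counts.tsv")
        record("design", out / "design.csv", len(design))
        record("truth", out / "truth.tsv", len(truth))
        record("counts", out / "counts.tsv", matrix.shape[0])
        report["stages"]["simulate"] = {
            "n_samples": len(design),
            "n_genes": matrix.shape[0],
            "sim_config": sim_cfg.to_dict(),
        }
    else:
        matrix = _expr.read_counts(config.counts_path)
        design = read_design(config.design_path)

    if not config.normalize:
        _write_report(report, out)
        return report

    tissues = list(pd.unique(design["tissue"]))
    profiles = []
    logmats: dict[str, pd.DataFrame] = {}
    genes_surviving: dict[str, int] = {}
    for tissue in tissues:
        sample_ids = design.loc[design["tissue"] == tissue, "sample_id"]
        sub = matrix.subset_samples(sample_ids)
        sub = _expr.filter_low_expression(sub, config.cpm_threshold, config.filter_min_samples)
        factors = _expr.tmm_factors(sub)
        logmat = _expr.log_cpm(sub, factors, config.prior_count)
        logmat = _expr.batch_center(logmat, design, preserve=("group", "sex"))
        logmats[tissue] = logmat
        genes_surviving[tissue] = logmat.shape[0]
        profiles.append(_expr.group_means(logmat, design, tissues=[tissue]))
        path = out / f"logcpm_{tissue}.tsv"
        logmat.rename_axis("gene_id").to_csv(path, sep="\t")
        record(f"logcpm_{tissue}", path, logmat.shape[0])
    profile_table = pd.concat(profiles, ignore_index=True)
    path = out / "group_means.tsv"
    profile_table.to_csv(path, sep="\t", index=False)
    record("group_means", path, len(profile_table))
    report["stages"]["normalize"] = {"genes_surviving_filter": genes_surviving}

    if not config.de:
        _write_report(report, out)
        return report

    deg_sets: dict[str, set[str]] = {}
    de_rows = 0
    de_frames = []
    for tissue in tissues:
        res = _de.de_test(logmats[tissue], design, tissue, 1, 4)
        de_frames.append(res)
        de_rows += len(res)
        deg_sets[tissue] = _de.deg_select(res, config.fdr, config.min_abs_log2fc)
    de_table = pd.concat(de_frames, ignore_index=True)
    path = out / "de_purebred_1v4.tsv"
    de_table.to_csv(path, sep="\t", index=False)
    record("de_purebred_1v4", path, de_rows)
    summary = _de.degs_across_tissues(deg_sets)
    venn = {
        "region_counts": summary.region_counts(),
        "shared_all": sorted(summary.shared_all),
        "tissue_specific_counts": {t: len(s) for t, s in summary.tissue_specific.items()},
    }
    (out / "venn.json").write_text(json.dumps(venn, indent=2))
    record("venn", out / "venn.json", len(summary.regions))
    report["stages"]["de"] = {
        "deg_counts": {t: len(s) for t, s in deg_sets.items()},
        "shared_all_tissues": len(summary.shared_all),
    }

    if config.classify:
        thresholds = config.thresholds()
        calls = _classify.classify_table(profile_table, deg_sets, thresholds)
        path = out / "inheritance_calls.tsv"
        calls.to_csv(path, sep="\t", index=False)
        record("inheritance_calls", path, len(calls))
        counts_table = _classify.category_counts(calls)
        path = out / "category_counts.tsv"
        counts_table.rename_axis("tissue").to_csv(path, sep="\t")
        record("category_counts", path, len(counts_table))
        report["stages"]["classify"] = {
            "n_calls": len(calls),
            "category_totals": {
                c: int(n)
                for c, n in calls["category"].value_counts().items()
            },
        }

    if config.context:
        annotation = read_annotation(config.annotation_path)
        lnc = annotation.loc[annotation["biotype"] == config.lnc_biotype, "gene_id"]
        coding = annotation.loc[annotation["biotype"] == "coding", "gene_id"]
        pairs = neighbor_pairs(annotation, lnc, coding, config.max_neighbor_distance)
        concordance = {}
        for tissue in tissues:
            de_sub = de_table[
                (de_table["tissue"] == tissue)
                & de_table["gene_id"].isin(deg_sets[tissue])
            ]
            res = direction_concordance(pairs, de_sub)
            concordance[tissue] = {
                "fraction_pairs_opposite": res.fraction_pairs_opposite,
                "n_pairs": res.n_pairs,
                "fraction_lnc_opposite": res.fraction_lnc_opposite,
                "n_lncrnas": res.n_lncrnas,
            }
        path = out / "neighbor_pairs.tsv"
        pairs.to_csv(path, sep="\t", index=False)
        record("neighbor_pairs", path, len(pairs))
        report["stages"]["context"] = concordance

    _write_report(report, out)
    return report


def _write_report(report: dict, out: Path) -> None:
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
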