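"""End-to-end orchestration: genotype filtering → relatedness → quantile
local/migrant classification → spatial mixture clustering → rIN/rOUT →
binary clustering into disperser categories → life-history traits →
cohort comparisons, with per-cohort execution, seeded determinism and a
single structured report."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import comparisons as cmp
from . import dispersal, lifehistory, relatedness, spatial
from .genotypes import GenotypeMatrix, filter_loci, locus_summaries, read_genotypes, read_metadata
from .simulate import SimulationConfig, SyntheticDataset, generate

__all__ = ["PipelineConfig", "CohortResult", "RunReport", "run_pipeline", "write_report"]

__version__ = "0.1.0"


@dataclass
class PipelineConfig:
    """Inputs and knobs for one pipeline run. Exactly one of ``simulation``
    or ``genotypes_path`` must be set."""

    seed: int = 0
    simulation: SimulationConfig | None = None
    genotypes_path: str | None = None
    genotype_format: str = "slash-call"
    metadata_path: str | None = None
    otoliths_path: str | None = None

    hwe_alpha: float = 0.05
    r2_max: float = 0.8
    q: float = 0.25
    r_threshold: float = 0.1
    k_list: tuple[int, ...] = (4, 5, 6)
    runs_per_k: int = 10
    mode: str = "order_preserving"
    season_year: int | None = None

    def __post_init__(self) -> None:
        has_sim = self.simulation is not None
        has_files = self.genotypes_path is not None
        if has_sim == has_files:
            raise ValueError("set exactly one of simulation or genotypes_path")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        sim = raw.pop("simulation", None)
        if sim is not None:
            sim = SimulationConfig(**sim)
        if "k_list" in raw:
            raw["k_list"] = tuple(raw["k_list"])
        return cls(simulation=sim, **raw)

    def config_hash(self) -> str:
        payload = {k: v for k, v in asdict(self).items()}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


@dataclass
class CohortResult:
    """All per-cohort artifacts of one pipeline run."""

    cohort: str
    n: int
    relatedness: relatedness.RelatednessMatrix
    ratio_classification: relatedness.RatioClassification
    clustering: spatial.SpatialClustering
    profiles: dispersal.InOutProfile
    embc: dispersal.EmbcModel
    assignment: dispersal.DisperserAssignment
    proportions: pd.DataFrame


@dataclass
class RunReport:
    """Structured summary of a run: stage counts, chosen models,
    per-cluster category proportion tables, comparisons, provenance."""

    seed: int
    config_hash: str
    version: str
    stage_counts: dict
    cohorts: dict[str, CohortResult]
    locus_filter_report: pd.DataFrame
    traits: pd.DataFrame | None
    age_length_model: lifehistory.AgeLengthModel | None
    comparisons: list[cmp.TestResult]

    def summary_dict(self) -> dict:
        out = {
            "seed": self.seed,
            "config_hash": self.config_hash,
            "version": self.version,
            "stage_counts": self.stage_counts,
            "cohorts": {},
            "comparisons": [
                {
                    "label": t.label,
                    "test": t.test,
                    "statistic": t.statistic,
                    "p_value": t.p_value,
                    "n1": t.n1,
                    "n2": t.n2,
                }
                for t in self.comparisons
            ],
        }
        if self.age_length_model is not None:
            out["age_length_model"] = {
                "slope": self.age_length_model.slope,
                "intercept": self.age_length_model.intercept,
                "pearson_r": self.age_length_model.pearson_r,
                "n": self.age_length_model.n,
            }
        for name, c in self.cohorts.items():
            out["cohorts"][name] = {
                "n": c.n,
                "chosen_K": c.clustering.n_clusters,
                "chosen_aic": c.clustering.fit.aic,
                "embc_delimiters": list(c.embc.delimiters),
                "n_locals": len(c.ratio_classification.locals_),
                "n_migrants": len(c.ratio_classification.migrants),
                "category_counts": c.assignment.counts(),
                "proportions": c.proportions.to_dict(orient="records"),
            }
        return out


def _check_conservation(cohort: CohortResult) -> None:
    t = cohort.assignment.table
    n_assigned = int((t["category"] != "UNASSIGNED").sum())
    n_unassigned = int((t["category"] == "UNASSIGNED").sum())
    if n_assigned + n_unassigned != cohort.n:
        raise AssertionError(
            f"count conservation violated in cohort {cohort.cohort}: "
            f"{n_assigned}+{n_unassigned} != {cohort.n}"
        )
    prop = cohort.proportions[list(dispersal.CATEGORIES)].sum(axis=1)
    if not np.allclose(prop, 1.0, atol=1e-9):
        raise AssertionError("category proportions do not sum to 1")


def _seed_stream(seed: int, name: str) -> int:
    h = hashlib.sha256(f"{seed}:{name}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def run_pipeline(config: PipelineConfig, outdir=None) -> RunReport:
    """Execute every stage per cohort and return a :class:`RunReport`.

    Deterministic given ``config.seed``: the spatial GMM, the binary
    clustering and the simulation each draw from named substreams of the
    root seed. With ``outdir`` set, all tables are also written to disk.
    """
    stage_counts: dict = {}
    otoliths = None
    if config.simulation is not None:
        sim_cfg = config.simulation
        dataset: SyntheticDataset | None = generate(sim_cfg)
        genotypes = dataset.genotypes
        metadata = dataset.metadata.copy()
        otoliths = dataset.otoliths
    else:
        dataset = None
        genotypes = read_genotypes(config.genotypes_path, format=config.genotype_format)
        metadata = read_metadata(config.metadata_path)
        if config.otoliths_path:
            otoliths = pd.read_csv(config.otoliths_path)
    metadata["collection_date"] = pd.to_datetime(metadata["collection_date"])
    stage_counts["input_individuals"] = genotypes.n_individuals
    stage_counts["input_loci"] = genotypes.n_loci

    filtered, filter_report = filter_loci(genotypes, config.hwe_alpha, config.r2_max)
    stage_counts["loci_after_filter"] = filtered.n_loci

    meta_by_id = metadata.set_index("id")
    cohorts: dict[str, CohortResult] = {}
    for cohort_name in pd.unique(metadata["stage"]):
        ids = meta_by_id.index[meta_by_id["stage"] == cohort_name]
        mask = np.array([i in set(ids) for i in filtered.individual_ids])
        sub = filtered.subset(individuals=mask)
        sub_meta = meta_by_id.loc[sub.individual_ids]

        rm = relatedness.qg_matrix(sub)
        ratios = relatedness.relatedness_ratio(rm, config.r_threshold)
        classification = relatedness.classify_locals_migrants(
            sub.individual_ids, ratios, q=config.q, r_threshold=config.r_threshold
        )
        points = spatial.project_coordinates(
            sub.individual_ids, sub_meta["lon"].to_numpy(), sub_meta["lat"].to_numpy(),
            cohort=str(cohort_name),
        )
        clustering = spatial.select_clustering(
            points,
            K_list=config.k_list,
            runs_per_K=config.runs_per_k,
            seed=_seed_stream(config.seed, f"gmm:{cohort_name}"),
        )
        norm = dispersal.normalize_relatedness(rm, mode=config.mode)
        profiles = dispersal.compute_rin_rout(norm, clustering)
        embc = dispersal.embc_fit(
            profiles.valid_xy(), seed=_seed_stream(config.seed, f"embc:{cohort_name}")
        )
        assignment = dispersal.assign_categories(embc, profiles)
        proportions = dispersal.category_proportions(assignment)
        result = CohortResult(
            cohort=str(cohort_name),
            n=sub.n_individuals,
            relatedness=rm,
            ratio_classification=classification,
            clustering=clustering,
            profiles=profiles,
            embc=embc,
            assignment=assignment,
            proportions=proportions,
        )
        _check_conservation(result)
        cohorts[str(cohort_name)] = result
    stage_counts["cohorts"] = {k: v.n for k, v in cohorts.items()}

    # life-history stage (needs otolith calibration data)
    traits_table = None
    model = None
    tests: list[cmp.TestResult] = []
    if otoliths is not None and len(otoliths) >= 3:
        oto = otoliths.merge(metadata[["id", "length_mm", "collection_date"]], on="id")
        model = lifehistory.calibrate_age_length(oto["length_mm"], oto["total_age_days"])
        ages, extrapolated = lifehistory.estimate_ages(model, metadata["length_mm"])
        measured = metadata["id"].map(oto.set_index("id")["total_age_days"])
        age_days = measured.fillna(pd.Series(ages, index=metadata.index)).astype(int)
        hatch = lifehistory.hatch_dates(metadata["collection_date"], age_days)
        year = config.season_year or int(metadata["collection_date"].dt.year.mode()[0])
        season = lifehistory.SeasonConfig(year=year)
        cohort_labels = lifehistory.assign_season_cohort(hatch, season)
        settle = lifehistory.assign_settlement_class(metadata["length_mm"], age_days)
        traits_table = pd.DataFrame(
            {
                "id": metadata["id"],
                "length_mm": metadata["length_mm"],
                "collection_date": metadata["collection_date"],
                "age_days": age_days,
                "age_extrapolated": extrapolated,
                "hatch_date": hatch,
                "season_cohort": cohort_labels,
                "settlement_class": settle,
            }
        )
        stage_counts["season_cohorts"] = pd.Series(cohort_labels).value_counts().to_dict()

        oto_traits = traits_table.set_index("id").loc[oto["id"]]
        r, pval = lifehistory.pld_hatchdate_correlation(
            oto["pld_days"], oto_traits["hatch_date"]
        )
        tests.append(
            cmp.TestResult(
                "pearson", r, pval, len(oto), len(oto),
                float(np.mean(oto["pld_days"])), 0.0, float(np.std(oto["pld_days"])), 0.0,
                label="pld_vs_hatch_day",
            )
        )
        early = oto["pld_days"][(oto_traits["season_cohort"] == "early").to_numpy()]
        late = oto["pld_days"][(oto_traits["season_cohort"] == "late").to_numpy()]
        if len(early) >= 2 and len(late) >= 2:
            tests.append(cmp.welch_t_test(early, late, label="pld_early_vs_late"))

    # spatial comparison: recent migrants vs the rest, per cohort
    for name, c in cohorts.items():
        pos = cmp.project_to_coastline_axis(c.clustering.points)
        mig = set(c.ratio_classification.migrants)
        is_mig = np.array([i in mig for i in c.clustering.points.individual_ids])
        if is_mig.sum() >= 3 and (~is_mig).sum() >= 3:
            tests.append(
                cmp.ks_two_sample(pos[is_mig], pos[~is_mig],
                                  label=f"migrants_vs_rest_position:{name}")
            )

    report = RunReport(
        seed=config.seed,
        config_hash=config.config_hash(),
        version=__version__,
        stage_counts=stage_counts,
        cohorts=cohorts,
        locus_filter_report=filter_report,
        traits=traits_table,
        age_length_model=model,
        comparisons=tests,
    )
    if outdir is not None:
        write_report(report, outdir)
    return report


def write_report(report: RunReport, outdir) -> None:
    """Write CSV tables per cohort plus one JSON summary and a short
    human-readable text summary."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    report.locus_filter_report.to_csv(out / "locus_filter.csv", index=False)
    for name, c in report.cohorts.items():
        c.relatedness.to_long_frame().to_csv(out / f"relatedness_{name}.csv", index=False)
        c.ratio_classification.table.to_csv(out / f"ratio_classification_{name}.csv", index=False)
        c.clustering.to_frame().to_csv(out / f"spatial_clusters_{name}.csv", index=False)
        c.assignment.table.to_csv(out / f"disperser_categories_{name}.csv", index=False)
        c.proportions.to_csv(out / f"category_proportions_{name}.csv", index=False)
        model = {
            "weights": c.embc.weights.tolist(),
            "means": c.embc.means.tolist(),
            "covariances": c.embc.covariances.tolist(),
            "codes": list(c.embc.codes),
            "delimiters": list(c.embc.delimiters),
            "seed": c.embc.seed,
        }
        (out / f"embc_model_{name}.json").write_text(json.dumps(model, indent=2))
        gmm = {
            "weights": c.clustering.fit.weights.tolist(),
            "means": c.clustering.fit.means.tolist(),
            "covariances": c.clustering.fit.covariances.tolist(),
            "aic": c.clustering.fit.aic,
            "seed": c.clustering.fit.seed,
        }
        (out / f"spatial_model_{name}.json").write_text(json.dumps(gmm, indent=2))
    if report.traits is not None:
        report.traits.to_csv(out / "traits.csv", index=False)
    (out / "summary.json").write_text(json.dumps(report.summary_dict(), indent=2, default=str))
    lines = [f"patchkin v{report.version}  seed={report.seed}  config={report.config_hash}"]
    for name, c in report.cohorts.items():
        lines.append(
            f"cohort {name}: N={c.n}, K={c.clustering.n_clusters} "
            f"(AIC={c.clustering.fit.aic:.1f}), "
            f"locals={len(c.ratio_classification.locals_)}, "
            f"migrants={len(c.ratio_classification.migrants)}"
        )
    for t in report.comparisons:
        lines.append(t.describe())
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
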