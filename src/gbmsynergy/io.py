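"""File formats, pipeline configuration, and end-to-end orchestration.

Formats: plate viability CSV (long format, or wide 384-well grid plus a
well-to-metadata layout map), limiting-dilution well-count CSV, TPM
expression TSV (genes x samples), phenotype sidecar TSV, GMT gene-set files,
and a JSON run manifest.  Doses are stored in µM throughout; readers accept
only explicitly unit-tagged columns (``dose_uM``) — no unit guessing.

Every output table is tab-separated with a fixed column order, floats at 10
significant digits, and a leading comment line carrying the run-manifest
hash, so reruns with identical inputs and seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .biomarkers import P_CUT, RHO_CUT, PanelPhenotypes, biomarker_pipeline
from .combination import (
    ADDITIVE_BAND,
    DEFAULT_FA_MIN,
    DoseMatrix,
    ci_grid,
    classify_interaction,
    correlate_sensitivity_synergy,
    isobologram,
    min_ci,
)
from .dose_response import (
    FA_CLIP,
    DoseResponseError,
    fit_median_effect,
    normalize_viability,
)
from .elda import WellCounts, estimate_frequency, pairwise_comparison_table
from .enrichment import GeneSetCollection, gsea_preranked, rank_genes_by_phenotype, ssgsea

__all__ = [
    "ParseError",
    "PipelineConfig",
    "read_plate_csv",
    "read_plate_wide",
    "read_wells_csv",
    "read_expression_tsv",
    "read_phenotypes_tsv",
    "read_gmt",
    "write_gmt",
    "combo_matrix_from_records",
    "run_pipeline",
]

log = logging.getLogger("gbmsynergy")

PLATE_COLUMNS = ["model_id", "agent", "dose_uM", "luminescence", "replicate"]
WELL_COLUMNS = ["group", "dose_cells", "n_wells", "n_positive"]


class ParseError(ValueError):
    """Input file violates the expected format; ``.lines`` lists bad rows."""

    def __init__(self, message: str, lines: list[int] | None = None):
        super().__init__(message)
        self.lines = lines or []


def read_plate_csv(path) -> pd.DataFrame:
    """Read a long-format plate viability CSV.

    Required columns: model_id, agent, dose_uM, luminescence, replicate.
    An optional dose2_uM column carries the partner dose of combination
    wells (absent or 0 for single-agent wells).  Malformed rows (non-numeric
    or negative dose/luminescence) are rejected with their line numbers.
    """
    df = pd.read_csv(path, comment="#")
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    bad: list[int] = []
    for col in ["dose_uM", "luminescence"] + (
        ["dose2_uM"] if "dose2_uM" in df.columns else []
    ):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad.extend((df.index[coerced.isna() | (coerced < 0)] + 2).tolist())
        df[col] = coerced
    if bad:
        lines = sorted(set(bad))
        raise ParseError(
            f"{path}: {len(lines)} malformed row(s) at line(s) {lines}", lines
        )
    if "dose2_uM" not in df.columns:
        df["dose2_uM"] = 0.0
    return df


def read_plate_wide(plate_path, layout_path, model_id: str) -> pd.DataFrame:
    """Read a wide 384-well plate grid plus a well layout map.

    The plate file is a luminescence grid with row letters A-P in the first
    column and column numbers 1-24 in the header.  The layout map is a CSV
    with columns well (e.g. ``B07``), agent, dose_uM, replicate and optional
    dose2_uM; unmapped wells are ignored.
    """
    grid = pd.read_csv(plate_path, index_col=0)
    layout = pd.read_csv(layout_path)
    need = {"well", "agent", "dose_uM", "replicate"}
    if not need <= set(layout.columns):
        raise ParseError(f"{layout_path}: layout map needs columns {sorted(need)}")
    rows = []
    for _, m in layout.iterrows():
        well = str(m["well"])
        row_letter, col = well[0], str(int(well[1:]))
        try:
            lum = float(grid.loc[row_letter, col])
        except KeyError as exc:
            raise ParseError(f"{plate_path}: well {well} not in plate grid") from exc
        rows.append(
            {
                "model_id": model_id,
                "agent": m["agent"],
                "dose_uM": float(m["dose_uM"]),
                "luminescence": lum,
                "replicate": int(m["replicate"]),
                "dose2_uM": float(m.get("dose2_uM", 0.0) or 0.0),
            }
        )
    return pd.DataFrame(rows, columns=PLATE_COLUMNS + ["dose2_uM"])


def read_wells_csv(path) -> list[WellCounts]:
    """Read limiting-dilution counts (group,dose_cells,n_wells,n_positive)."""
    df = pd.read_csv(path, comment="#")
    missing = [c for c in WELL_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    groups = []
    for name, sub in df.groupby("group", sort=True):
        groups.append(
            WellCounts(
                dose=sub["dose_cells"].to_numpy(float),
                n_wells=sub["n_wells"].to_numpy(int),
                n_positive=sub["n_positive"].to_numpy(int),
                group=str(name),
            )
        )
    return groups


def read_expression_tsv(path) -> pd.DataFrame:
    """Read a genes x samples TPM matrix (tab-separated, gene ids in column 1)."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicate gene ids {dup[:5]}")
    if (df.to_numpy(float) < 0).any():
        raise ParseError(f"{path}: negative TPM values")
    return df


def read_phenotypes_tsv(path) -> pd.DataFrame:
    """Read the per-sample phenotype sidecar (sample, ci, ic50_uM, subtype...)."""
    return pd.read_csv(path, sep="\t", index_col=0, comment="#")


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT gene-set file (name TAB description TAB gene1 TAB ...).

    Duplicate genes within a set are de-duplicated with a warning; empty
    sets and duplicate set names are rejected.
    """
    sets: dict[str, tuple[str, ...]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{ln}: set has no genes", [ln])
            name, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            if not genes:
                raise ParseError(f"{path}:{ln}: set {name!r} is empty", [ln])
            if name in sets:
                raise ParseError(f"{path}:{ln}: duplicate set name {name!r}", [ln])
            unique = list(dict.fromkeys(genes))
            if len(unique) != len(genes):
                log.warning("%s:%d: set %s has duplicate genes; de-duplicated",
                            path, ln, name)
            sets[name] = tuple(unique)
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def combo_matrix_from_records(
    records: pd.DataFrame, model_id: str, agent: str
) -> DoseMatrix:
    """Build a combination DoseMatrix from long-format combination rows.

    Combination wells are rows for ``agent`` with dose2_uM > 0; fa per cell
    is 1 - mean(lum)/mean(control lum), clipped to [0, 1].
    """
    sub = records[records["model_id"] == model_id]
    ctrl = sub.loc[sub["dose_uM"] == 0, "luminescence"]
    if len(ctrl) == 0 or ctrl.mean() <= 0:
        raise DoseResponseError("no-control", f"no vehicle control for {model_id!r}")
    combo = sub[(sub["agent"] == agent) & (sub["dose2_uM"] > 0) & (sub["dose_uM"] > 0)]
    if combo.empty:
        raise ParseError(f"no combination rows for model {model_id!r}, agent {agent!r}")
    g = combo.groupby(["dose_uM", "dose2_uM"])["luminescence"].mean().unstack()
    fa = np.clip(1.0 - g.to_numpy() / float(ctrl.mean()), 0.0, 1.0)
    return DoseMatrix(
        drug1_doses=g.index.to_numpy(float),
        drug2_doses=g.columns.to_numpy(float),
        fa_grid=fa,
        model_id=model_id,
    )


# ---------------------------------------------------------------------------
# pipeline configuration and orchestration


@dataclass
class PipelineConfig:
    """Declarative configuration for the end-to-end run.

    Defaults follow the analysis conventions: rho_cut 0.2 and p_cut 0.1 at
    the biomarker gate, FDR 0.05 downstream, additive band [0.9, 1.1],
    min-CI effect floor 0.2, fa clip 1e-4, 10,000 GSEA permutations.
    """

    # inputs
    plate_csv: str | None = None
    wells_csv: str | None = None
    expression_tsv: str | None = None
    phenotypes_tsv: str | None = None
    gmt: str | None = None
    combo_agent: str | None = None  # agent label of combination rows
    # stage toggles
    stages: tuple[str, ...] = ("fit", "ci", "elda", "gsea", "ssgsea", "biomarkers")
    # parameters
    seed: int = 0
    fa_clip: float = FA_CLIP
    fa_min: float = DEFAULT_FA_MIN
    additive_band: tuple[float, float] = ADDITIVE_BAND
    n_perm: int = 10000
    rho_cut: float = RHO_CUT
    p_cut: float = P_CUT
    conf: float = 0.95
    rank_phenotype: str = "ic50_uM"  # phenotype column for GSEA ranking
    outdir: str = "results"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ParseError(f"{path}: unknown config keys {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        if "additive_band" in raw:
            raw["additive_band"] = tuple(raw["additive_band"])
        return cls(**raw)

    def validate(self) -> None:
        need = {
            "fit": ["plate_csv"],
            "ci": ["plate_csv"],
            "elda": ["wells_csv"],
            "gsea": ["expression_tsv", "phenotypes_tsv", "gmt"],
            "ssgsea": ["expression_tsv", "gmt"],
            "biomarkers": ["expression_tsv", "phenotypes_tsv", "gmt"],
        }
        for stage in self.stages:
            if stage not in need:
                raise ParseError(f"unknown stage {stage!r}")
            for inp in need[stage]:
                val = getattr(self, inp)
                if val is None:
                    raise ParseError(f"stage {stage!r} requires {inp}")
                if not Path(val).exists():
                    raise ParseError(f"stage {stage!r} input not found: {val}")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_table(df: pd.DataFrame, path: Path, manifest_hash: str,
                 index: bool = False, index_label=None) -> None:
    with open(path, "w") as fh:
        fh.write(f"# run_manifest_sha256={manifest_hash}\n")
        df.to_csv(fh, sep="\t", float_format="%.10g", index=index,
                  index_label=index_label)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages end to end and write all result tables.

    Fails fast on configuration errors before any compute; a stage failure
    aborts with a stage-tagged error while earlier outputs are retained.
    Returns the in-memory result bundle keyed by stage.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    inputs = {
        k: getattr(config, k)
        for k in ("plate_csv", "wells_csv", "expression_tsv", "phenotypes_tsv", "gmt")
        if getattr(config, k)
    }
    path_fields = set(inputs) | {"outdir"}
    manifest = {
        "version": __version__,
        "parameters": {
            k: v for k, v in asdict(config).items() if k not in path_fields
        },
        "inputs": {k: {"path": v, "sha256": _sha256(v)} for k, v in inputs.items()},
        "outdir": config.outdir,
    }
    # identity hash covers parameters and input *content* only, so reruns with
    # identical inputs and seed are byte-identical wherever they write
    core = {
        "version": manifest["version"],
        "parameters": manifest["parameters"],
        "inputs": {k: v["sha256"] for k, v in manifest["inputs"].items()},
    }
    manifest_hash = hashlib.sha256(
        json.dumps(core, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    manifest["manifest_sha256"] = manifest_hash

    results: dict = {"manifest": manifest}
    fits: dict[tuple[str, str], object] = {}

    try:
        if "fit" in config.stages or "ci" in config.stages:
            stage = "fit"
            records = read_plate_csv(config.plate_csv)
            single = records[(records["dose_uM"] > 0) & (records["dose2_uM"] == 0)]
            rows = []
            for (model, agent), _ in single.groupby(["model_id", "agent"]):
                effect = normalize_viability(records, model, agent)
                fit = fit_median_effect(effect, clip=config.fa_clip)
                fits[(model, agent)] = fit
                rows.append(
                    {"model_id": model, "agent": agent, "m": fit.m,
                     "Dm_uM": fit.Dm, "r_linfit": fit.r_linfit,
                     "n_points": fit.n_points_used, "flags": ";".join(fit.flags)}
                )
            fit_table = pd.DataFrame(rows)
            results["fit"] = fit_table
            _write_table(fit_table, outdir / "median_effect_fits.tsv", manifest_hash)
            log.info("stage fit: %d single-agent fits", len(rows))

        if "ci" in config.stages:
            stage = "ci"
            agents = sorted({a for (_, a) in fits})
            combo_agent = config.combo_agent or (agents[0] if agents else None)
            ci_rows, summary_rows, iso_frames = [], [], []
            for model in sorted({m for (m, _) in fits}):
                if (model, combo_agent) not in fits or len(
                    [a for (mm, a) in fits if mm == model]
                ) < 2:
                    continue
                partner = next(
                    a for (mm, a) in fits if mm == model and a != combo_agent
                )
                try:
                    matrix = combo_matrix_from_records(records, model, combo_agent)
                except ParseError:
                    continue
                grid = ci_grid(
                    matrix, fits[(model, combo_agent)], fits[(model, partner)],
                    clip=config.fa_clip,
                )
                for p in grid:
                    ci_rows.append(
                        {"model_id": model, "d1_uM": p.d1, "d2_uM": p.d2,
                         "fa": p.fa, "Dx1_uM": p.Dx1, "Dx2_uM": p.Dx2,
                         "ci": p.ci, "flag": ";".join(p.flags)}
                    )
                lowest, best = min_ci(grid, fa_min=config.fa_min)
                lowest_any, _ = min_ci(grid, fa_min=0.0)
                call = classify_interaction(lowest, band=config.additive_band)
                summary_rows.append(
                    {"model_id": model, "min_ci": lowest,
                     "min_ci_unrestricted": lowest_any,
                     "at_d1_uM": best.d1, "at_d2_uM": best.d2, "at_fa": best.fa,
                     "interaction": call.label}
                )
                iso = isobologram(grid)
                iso.insert(0, "model_id", model)
                iso_frames.append(iso)
            results["ci"] = pd.DataFrame(ci_rows)
            results["ci_summary"] = pd.DataFrame(summary_rows)
            _write_table(results["ci"], outdir / "combination_index.tsv", manifest_hash)
            _write_table(results["ci_summary"], outdir / "ci_summary.tsv", manifest_hash)
            if iso_frames:
                _write_table(pd.concat(iso_frames, ignore_index=True),
                             outdir / "isobologram_points.tsv", manifest_hash)
            if len(summary_rows) >= 3 and "fit" in results:
                merged = results["ci_summary"].merge(
                    results["fit"].query("agent == @combo_agent")[
                        ["model_id", "Dm_uM"]
                    ],
                    on="model_id",
                )
                corr = correlate_sensitivity_synergy(
                    merged["Dm_uM"], merged["min_ci"]
                )
                results["sensitivity_synergy"] = corr
                _write_table(
                    pd.DataFrame([{"pearson_r": corr.r, "p": corr.p, "n": corr.n}]),
                    outdir / "sensitivity_synergy_correlation.tsv", manifest_hash,
                )
            log.info("stage ci: %d models summarized", len(summary_rows))

        if "elda" in config.stages:
            stage = "elda"
            groups = read_wells_csv(config.wells_csv)
            est_rows = []
            for g in groups:
                est = estimate_frequency(g, conf=config.conf)
                est_rows.append(
                    {"group": g.group, "f": est.f, "one_in": est.one_in,
                     "ci_low": est.ci_low, "ci_high": est.ci_high,
                     "flag": ";".join(est.flags)}
                )
            results["elda"] = pd.DataFrame(est_rows)
            _write_table(results["elda"], outdir / "elda_frequencies.tsv", manifest_hash)
            if len(groups) >= 2:
                results["elda_pairwise"] = pairwise_comparison_table(groups)
                _write_table(results["elda_pairwise"],
                             outdir / "elda_pairwise.tsv", manifest_hash)
            log.info("stage elda: %d groups", len(groups))

        if set(config.stages) & {"gsea", "ssgsea", "biomarkers"}:
            expr = read_expression_tsv(config.expression_tsv)
            collection = read_gmt(config.gmt)

        if "gsea" in config.stages:
            stage = "gsea"
            pheno = read_phenotypes_tsv(config.phenotypes_tsv)
            ranked = rank_genes_by_phenotype(expr, pheno[config.rank_phenotype])
            results["gsea"] = gsea_preranked(
                ranked, collection, n_perm=config.n_perm, seed=config.seed
            )
            _write_table(results["gsea"], outdir / "gsea.tsv", manifest_hash)
            log.info("stage gsea: %d sets tested", len(results["gsea"]))

        if "ssgsea" in config.stages:
            stage = "ssgsea"
            results["ssgsea"] = ssgsea(expr, collection)
            _write_table(results["ssgsea"], outdir / "ssgsea.tsv", manifest_hash,
                         index=True, index_label="set")
            log.info("stage ssgsea: %d sets scored", len(results["ssgsea"]))

        if "biomarkers" in config.stages:
            stage = "biomarkers"
            pheno = read_phenotypes_tsv(config.phenotypes_tsv)
            panel = PanelPhenotypes(
                ci=pheno["ci"], ic50=pheno["ic50_uM"], subtype=pheno["subtype"]
            )
            bundle = biomarker_pipeline(
                expr, panel, collection, rho_cut=config.rho_cut, p_cut=config.p_cut
            )
            results["biomarkers"] = bundle
            _write_table(bundle["ancova"], outdir / "ancova.tsv", manifest_hash,
                         index=True, index_label="gene")
            _write_table(bundle["ora_synergy"], outdir / "ora_synergy.tsv",
                         manifest_hash)
            _write_table(bundle["ora_additive"], outdir / "ora_additive.tsv",
                         manifest_hash)
            log.info(
                "stage biomarkers: %d synergy / %d additive genes",
                len(bundle["synergy_genes"]), len(bundle["additive_genes"]),
            )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return results
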