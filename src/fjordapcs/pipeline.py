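"""End-to-end orchestration of the source-apportionment analysis.

One config drives: below-LOD imputation -> fjord-row standardization ->
PCA -> component retention -> varimax rotation -> broken-stick loading
significance -> component independence check -> Ward clustering of
loadings -> APCS-MLR contribution shares -> mixing-component endmember
regressions -> river endmembers -> per-station freshwater content.  All
stage outputs are written as CSV/JSON under an output directory together
with a manifest recording the seed and every decision taken, so a run is
reproducible from config + inputs alone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import apcs as apcs_mod
from . import geochem
from .clusters import cluster_loadings
from .endmembers import (endmember_regression, partial_values,
                         river_endmember)
from .factors import (fit_pca, pc_independence_test, retain_components,
                      significant_loadings, varimax_rotate)
from .hydrography import (DepthProfile, REFERENCE_SALINITY,
                          classify_water_mass, freshwater_content,
                          specific_freshwater_content)

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger("fjordapcs")


@dataclass
class PipelineConfig:
    """Everything needed to reproduce a run."""

    input_table: str | None = None
    input_schema: str | None = None
    output_dir: str = "fjordapcs_out"
    parameter_subset: list[str] | None = None
    seed: int = geochem.DEFAULT_IMPUTATION_SEED
    retention_rule: str = "guttman_kaiser"
    fixed_k: int | None = None
    n_clusters: int = 5
    mask_insignificant_for_clustering: bool = True
    alpha_drop: float = 0.1
    s_ref: float = REFERENCE_SALINITY
    endmember_component: str = "PC1"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


def run_pipeline(config: PipelineConfig,
                 table: geochem.GeochemTable | None = None) -> dict:
    """Execute every stage; returns the manifest (also written to disk).

    ``table`` may be passed directly (e.g. a synthetic one); otherwise it is
    read from ``config.input_table`` / ``config.input_schema``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "warnings": [], "stages": []}

    def stage(name):
        logger.info("stage: %s", name)
        manifest["stages"].append(name)

    try:
        if table is None:
            stage("read_table")
            if config.input_table is None:
                raise ValueError("no input table given")
            table = geochem.read_table(config.input_table, config.input_schema)

        stage("impute_below_lod")
        table = geochem.impute_below_lod(table, seed=config.seed)
        geochem.write_table(table, out / "table_imputed.csv")

        stage("standardize")
        fjord = table.subset("fjord")
        z, std = standardize_with_subset(fjord, config.parameter_subset)
        z.to_csv(out / "z_matrix.csv")

        stage("pca")
        model = fit_pca(z)
        if config.retention_rule == "fixed_k":
            k = retain_components(model, "fixed_k", k=config.fixed_k)
        else:
            k = retain_components(model, config.retention_rule)
        manifest["eigenvalues"] = [float(v) for v in model.eigenvalues]
        manifest["k_retained"] = int(k)

        stage("varimax_rotate")
        if k >= 2:
            rotated = varimax_rotate(model, k)
        else:
            rotated = varimax_rotate(model, max(k, 1))
            manifest["warnings"].append(
                "k < 2: rotation skipped (undefined for one component)")
        manifest["variance_fraction"] = [
            float(v) for v in rotated.variance_fraction]
        rotated.loadings.to_csv(out / "loadings.csv")
        rotated.scores.to_csv(out / "scores.csv")
        np.savetxt(out / "eigenvalues.csv", model.eigenvalues, delimiter=",")

        stage("loading_significance")
        sig = significant_loadings(rotated)
        sig.significant.astype(int).to_csv(out / "loading_significance.csv")

        stage("independence_test")
        if rotated.k >= 2:
            indep = pc_independence_test(rotated.scores)
            indep.to_csv(out / "independence_test.csv", index=False)
            manifest["independence_rejections"] = int(
                (indep["decision"] == "reject").sum())

        stage("cluster_loadings")
        mask = sig if config.mask_insignificant_for_clustering else None
        n_clusters = min(config.n_clusters, rotated.p)
        assignment = cluster_loadings(rotated.loadings, n_clusters, mask)
        assignment.labels.to_csv(out / "clusters.csv")
        (out / "cluster_tree.nwk").write_text(assignment.to_newick())
        manifest["n_clusters"] = int(assignment.n_clusters)

        stage("apcs_mlr")
        result = apcs_mod.apportion(fjord.values[z.columns], rotated, std,
                                    alpha_drop=config.alpha_drop)
        result.summary_table(rotated.loadings).to_csv(
            out / "apportionment.csv")
        diagnostics = {
            name: {
                "intercept": rec.intercept,
                "coefficients": rec.coefficients,
                "p_values": rec.p_values,
                "codes": rec.codes,
                "retained": rec.retained,
                "r_squared": rec.r_squared,
            }
            for name, rec in result.fits.items()
        }
        (out / "apportionment.json").write_text(
            json.dumps(diagnostics, indent=1))

        stage("endmembers")
        endmember_rows = []
        if config.endmember_component in rotated.loadings.columns:
            partial, excluded = partial_values(
                rotated, std, config.endmember_component, sig)
            salinity = fjord.values["salinity"] \
                if "salinity" in fjord.values.columns else None
            if salinity is not None:
                for name in partial.columns:
                    est = endmember_regression(
                        partial[name], salinity, s_marine=config.s_ref,
                        parameter=name)
                    endmember_rows.append({
                        "parameter": name, "slope": est.slope,
                        "intercept": est.intercept,
                        "endmember_s0": est.endmember_s0,
                        f"endmember_s{config.s_ref}": est.endmember_marine,
                        "r_squared": est.r_squared,
                        "negative_flag": est.negative_flag,
                    })
            manifest["endmember_excluded"] = excluded
        try:
            rivers = table.subset("river")
            for name in rivers.values.columns:
                vals = rivers.values[name].dropna()
                if len(vals) >= 2:
                    rv = river_endmember(vals, parameter=name)
                    for row in endmember_rows:
                        if row["parameter"] == name:
                            row["river_mean"] = rv.mean
                            row["river_sd"] = rv.sd
        except ValueError:
            manifest["warnings"].append("no river samples; river endmembers "
                                        "skipped")
        pd.DataFrame(endmember_rows).to_csv(out / "endmembers.csv",
                                            index=False)

        stage("hydrography")
        hydro_rows = []
        for station, grp in fjord.observations.groupby("station"):
            grp = grp.sort_values("depth_m")
            sal = fjord.values.loc[grp.index, "salinity"] \
                if "salinity" in fjord.values.columns else None
            if sal is None:
                break
            profile = DepthProfile(
                station=station,
                depths=grp["depth_m"].to_numpy(),
                salinities=sal.to_numpy(),
            )
            fwc = freshwater_content(profile, s_ref=config.s_ref)
            row = {"station": station, "fwc_m": fwc,
                   "fwc_sp_percent": specific_freshwater_content(
                       fwc, profile.bottom_depth)}
            if "temperature" in fjord.values.columns:
                temps = fjord.values.loc[grp.index, "temperature"]
                labels = [classify_water_mass(t, s)
                          for t, s in zip(temps, sal)]
                row["modal_water_mass"] = max(set(labels), key=labels.count)
            hydro_rows.append(row)
        pd.DataFrame(hydro_rows).to_csv(out / "freshwater_content.csv",
                                        index=False)
    except Exception as exc:
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise

    manifest["seed"] = int(config.seed)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def standardize_with_subset(fjord, subset):
    cols = subset if subset else None
    return geochem.standardize(fjord, cols)
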