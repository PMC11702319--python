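"""Station x depth x parameter geochemistry table: I/O, censored-value
imputation, and (de-)standardization.

The table holds one row per water sample (fjord water column or terrestrial
river outlet) and one column per measured parameter (salinity, temperature,
macronutrients, carbonate-system master variables AT/CT, and dissolved trace
elements).  Analytical detection limits are carried per parameter so that
censored ("< LOD") observations can be imputed reproducibly before
multivariate analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ParameterMeta",
    "GeochemTable",
    "StandardizationModel",
    "read_table",
    "write_table",
    "impute_below_lod",
    "standardize",
    "destandardize",
    "DEFAULT_IMPUTATION_SEED",
]

# Default seed for the below-LOD imputation draws; any caller-supplied seed
# overrides it.  Fixed so that a bare pipeline run is reproducible.
DEFAULT_IMPUTATION_SEED = 20200701

#: flag vocabulary for each cell of the table
FLAG_MEASURED = "measured"
FLAG_BELOW_LOD = "below_lod"
FLAG_IMPUTED = "imputed"
FLAG_MISSING = "missing"

SAMPLE_TYPES = ("fjord", "river")

#: parameters that are physical properties rather than concentrations and
#: therefore may legitimately be negative (temperature) or bounded (salinity)
PROPERTY_KINDS = ("property", "concentration")


@dataclass
class ParameterMeta:
    """Units and censoring metadata for one measured parameter."""

    name: str
    unit: str = ""
    lod: float | None = None
    loq: float | None = None
    kind: str = "concentration"  # "concentration" or "property"

    def __post_init__(self) -> None:
        if self.kind not in PROPERTY_KINDS:
            raise ValueError(f"unknown parameter kind {self.kind!r} for {self.name}")


@dataclass
class GeochemTable:
    """Observations (rows) by parameters (columns) with censoring flags.

    Attributes
    ----------
    observations : pd.DataFrame
        Indexed by unique ``sample_id``; columns ``station``, ``depth_m``,
        ``sample_type`` ("fjord" or "river").
    values : pd.DataFrame
        n x p numeric matrix, same index as ``observations``; NaN wherever
        the flag is ``below_lod`` or ``missing``.
    flags : pd.DataFrame
        n x p matrix of strings from {measured, below_lod, imputed, missing}.
    parameters : dict[str, ParameterMeta]
        Metadata keyed by parameter name, in column order of ``values``.
    provenance : dict
        Free-form record of how the table was produced (imputation seed,
        counts, source path).
    """

    observations: pd.DataFrame
    values: pd.DataFrame
    flags: pd.DataFrame
    parameters: dict[str, ParameterMeta]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        if len(self.observations) == 0:
            raise ValueError("no observations")
        if not self.observations.index.is_unique:
            dupes = self.observations.index[self.observations.index.duplicated()]
            raise ValueError(f"duplicate sample_id: {sorted(set(dupes))}")
        if self.values.shape != self.flags.shape:
            raise ValueError("values and flags matrices differ in shape")
        if list(self.values.columns) != list(self.flags.columns):
            raise ValueError("values and flags column order differ")
        unknown = set(self.values.columns) - set(self.parameters)
        if unknown:
            raise ValueError(f"parameters without metadata: {sorted(unknown)}")
        bad_type = set(self.observations["sample_type"]) - set(SAMPLE_TYPES)
        if bad_type:
            raise ValueError(f"unknown sample types: {sorted(bad_type)}")
        if (self.observations["depth_m"] < 0).any():
            raise ValueError("negative sampling depth")
        for name in self.values.columns:
            meta = self.parameters[name]
            col = self.values[name]
            measured = self.flags[name] == FLAG_MEASURED
            if meta.kind == "concentration" and (col[measured] < 0).any():
                bad = col.index[measured & (col < 0)][0]
                raise ValueError(
                    f"negative concentration for {name!r} in sample {bad!r}"
                )
            if name.lower() == "salinity":
                vals = col[measured]
                if ((vals < 0) | (vals > 42)).any():
                    raise ValueError("salinity outside [0, 42]")
            imputed = self.flags[name] == FLAG_IMPUTED
            if imputed.any():
                if meta.lod is None:
                    raise ValueError(f"imputed cells but no LOD for {name!r}")
                vals = col[imputed]
                if ((vals < 0) | (vals > meta.lod)).any():
                    raise ValueError(f"imputed value outside [0, lod) for {name!r}")

    # -- convenience --------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.observations)

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def subset(self, sample_type: str) -> "GeochemTable":
        """Return the fjord or river rows as a new table."""
        keep = self.observations["sample_type"] == sample_type
        if not keep.any():
            raise ValueError(f"no observations of type {sample_type!r}")
        return GeochemTable(
            observations=self.observations.loc[keep].copy(),
            values=self.values.loc[keep].copy(),
            flags=self.flags.loc[keep].copy(),
            parameters=dict(self.parameters),
            provenance=dict(self.provenance),
        )


@dataclass
class StandardizationModel:
    """Column means and sample SDs (divisor n-1) used to build a Z-matrix."""

    mean: pd.Series
    sd: pd.Series

    def __post_init__(self) -> None:
        if (self.sd <= 0).any():
            bad = list(self.sd.index[self.sd <= 0])
            raise ValueError(f"non-positive SD for parameters {bad}")

    @property
    def parameters(self) -> list[str]:
        return list(self.mean.index)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_ROLE_KEYS = ("sample_id", "station", "depth", "type")


def _load_schema(schema) -> dict:
    if isinstance(schema, (str, Path)):
        with open(schema) as fh:
            schema = yaml.safe_load(fh)
    if not isinstance(schema, dict):
        raise ValueError("schema must be a mapping or a path to a YAML mapping")
    for key in _ROLE_KEYS:
        if key not in schema:
            raise ValueError(f"schema is missing required column mapping {key!r}")
    if "parameters" not in schema or not schema["parameters"]:
        raise ValueError("schema declares no parameters")
    return schema


def read_table(path, schema) -> GeochemTable:
    """Read a delimited text table into a :class:`GeochemTable`.

    ``schema`` maps metadata roles and parameter names to file columns and
    declares units and detection limits::

        sample_id: ID
        station: Station
        depth: Depth_m
        type: Type
        parameters:
          dFe: {column: dFe_ngL, unit: "ng/L", lod: 12.0, kind: concentration}

    Cells that read ``<LOD`` (case-insensitive, optional spaces) are flagged
    ``below_lod``; blank cells are flagged ``missing``.
    """
    schema = _load_schema(schema)
    sep = schema.get("delimiter")
    raw = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c",
                      dtype=str, skipinitialspace=True)
    raw.columns = [c.strip() for c in raw.columns]
    if len(raw) == 0:
        raise ValueError("no observations")

    for key in _ROLE_KEYS:
        if schema[key] not in raw.columns:
            raise ValueError(f"column {schema[key]!r} for role {key!r} not in file")

    obs = pd.DataFrame(
        {
            "station": raw[schema["station"]].str.strip().to_numpy(),
            "depth_m": pd.to_numeric(raw[schema["depth"]]).to_numpy(),
            "sample_type": raw[schema["type"]].str.strip().str.lower()
                                              .to_numpy(),
        },
        index=pd.Index(raw[schema["sample_id"]].str.strip().to_numpy(),
                       name="sample_id"),
    )
    if not obs.index.is_unique:
        dupes = sorted(set(obs.index[obs.index.duplicated()]))
        raise ValueError(f"duplicate sample_id: {dupes}")

    parameters: dict[str, ParameterMeta] = {}
    values = {}
    flags = {}
    for name, spec in schema["parameters"].items():
        spec = spec or {}
        col = spec.get("column", name)
        if col not in raw.columns:
            raise ValueError(f"column {col!r} for parameter {name!r} not in file")
        parameters[name] = ParameterMeta(
            name=name,
            unit=str(spec.get("unit", "")),
            lod=spec.get("lod"),
            loq=spec.get("loq"),
            kind=spec.get("kind", "concentration"),
        )
        cells = raw[col].astype(str).str.strip()
        is_blank = cells.isin(["", "nan", "NaN", "NA"])
        is_cens = cells.str.replace(" ", "").str.lower() == "<lod"
        vals = pd.to_numeric(cells.where(~(is_blank | is_cens)), errors="raise")
        flag = np.where(is_cens, FLAG_BELOW_LOD,
                        np.where(is_blank, FLAG_MISSING, FLAG_MEASURED))
        values[name] = vals.to_numpy(dtype=float)
        flags[name] = flag
    values = pd.DataFrame(values, index=obs.index)
    flags = pd.DataFrame(flags, index=obs.index)
    return GeochemTable(
        observations=obs,
        values=values,
        flags=flags,
        parameters=parameters,
        provenance={"source": str(path)},
    )


def write_table(table: GeochemTable, path, sidecar=None) -> None:
    """Write the table as CSV plus a JSON sidecar with flags and provenance."""
    path = Path(path)
    out = pd.concat([table.observations, table.values], axis=1)
    out.to_csv(path, index_label="sample_id")
    sidecar = Path(sidecar) if sidecar else path.with_suffix(".json")
    payload = {
        "parameters": {
            name: {"unit": m.unit, "lod": m.lod, "loq": m.loq, "kind": m.kind}
            for name, m in table.parameters.items()
        },
        "flags": {c: table.flags[c].tolist() for c in table.flags.columns},
        "sample_ids": list(table.observations.index),
        "provenance": table.provenance,
    }
    with open(sidecar, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_written_table(path, sidecar=None) -> GeochemTable:
    """Inverse of :func:`write_table` (round-trips values, flags and units)."""
    path = Path(path)
    sidecar = Path(sidecar) if sidecar else path.with_suffix(".json")
    with open(sidecar) as fh:
        payload = json.load(fh)
    frame = pd.read_csv(path, index_col="sample_id")
    obs = frame[["station", "depth_m", "sample_type"]]
    params = {
        name: ParameterMeta(name=name, **spec)
        for name, spec in payload["parameters"].items()
    }
    values = frame[list(params)]
    flags = pd.DataFrame(
        {c: payload["flags"][c] for c in params}, index=obs.index
    )
    return GeochemTable(
        observations=obs, values=values, flags=flags, parameters=params,
        provenance=payload.get("provenance", {}),
    )


# ---------------------------------------------------------------------------
# Below-LOD imputation
# ---------------------------------------------------------------------------

def impute_below_lod(table: GeochemTable, seed: int = DEFAULT_IMPUTATION_SEED
                     ) -> GeochemTable:
    """Replace censored cells with uniform draws on [0, LOD).

    Censored analytical values carry only the information "somewhere between
    zero and the detection limit"; a uniform draw on that interval is the
    minimal-assumption replacement.  The draw is deterministic for a given
    seed, and draws scale linearly with the LOD (one standard-uniform deviate
    per cell, multiplied by the cell's LOD), so scaling every LOD by ``c``
    scales the imputed values by ``c``.
    """
    rng = np.random.default_rng(seed)
    values = table.values.copy()
    flags = table.flags.copy()
    n_imputed = 0
    for name in values.columns:
        cens = flags[name] == FLAG_BELOW_LOD
        if not cens.any():
            continue
        lod = table.parameters[name].lod
        if lod is None:
            raise ValueError(f"below-LOD cells but no LOD defined for {name!r}")
        draws = rng.random(int(cens.sum())) * lod
        values.loc[cens, name] = draws
        flags.loc[cens, name] = FLAG_IMPUTED
        n_imputed += int(cens.sum())
    prov = dict(table.provenance)
    prov.update({"imputation_seed": int(seed), "n_imputed": n_imputed})
    return GeochemTable(
        observations=table.observations.copy(),
        values=values,
        flags=flags,
        parameters=dict(table.parameters),
        provenance=prov,
    )


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------

def standardize(table: GeochemTable, parameter_subset=None
                ) -> tuple[pd.DataFrame, StandardizationModel]:
    """Z-score the selected parameter columns (sample SD, divisor n-1).

    Censored cells must have been imputed first; missing cells are rejected
    because the downstream eigen-decomposition has no missing-data treatment.
    """
    cols = list(parameter_subset) if parameter_subset is not None \
        else list(table.values.columns)
    unknown = [c for c in cols if c not in table.values.columns]
    if unknown:
        raise ValueError(f"unknown parameters: {unknown}")
    if table.n < 3:
        raise ValueError("need at least 3 observations to standardize")
    block = table.values[cols]
    bad_flags = table.flags[cols].isin([FLAG_BELOW_LOD, FLAG_MISSING])
    if bad_flags.any().any():
        offending = [c for c in cols if bad_flags[c].any()]
        raise ValueError(
            f"unresolved censored/missing values in {offending}; impute first"
        )
    mean = block.mean()
    sd = block.std(ddof=1)
    constant = sd.index[~(sd > 0)]
    if len(constant):
        raise ValueError(f"constant column(s): {list(constant)}")
    model = StandardizationModel(mean=mean, sd=sd)
    z = (block - mean) / sd
    return z, model


def destandardize(m, model: StandardizationModel) -> pd.DataFrame:
    """Map a matrix in Z-units back to original units (M * sd + mean)."""
    if isinstance(m, pd.DataFrame):
        missing = [c for c in m.columns if c not in model.mean.index]
        if missing:
            raise ValueError(f"model does not cover columns {missing}")
        return m * model.sd[m.columns] + model.mean[m.columns]
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[1] != len(model.mean):
        raise ValueError(
            f"column-count mismatch: matrix has {m.shape[-1]} columns, "
            f"model covers {len(model.mean)}"
        )
    return pd.DataFrame(
        m * model.sd.to_numpy() + model.mean.to_numpy(),
        columns=model.parameters,
    )
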