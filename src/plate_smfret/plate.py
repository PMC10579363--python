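"""Plate-level orchestration: layouts, per-well analysis, QC.

A plate layout is a CSV with a ``well_id`` column (``A01`` … ``H12`` for the
default 96-well geometry); every other column is preserved as a condition
variable ([NaCl], [GdmCl], [SSB], [RecA], [drug], variant, …).  The pipeline
runs burst search → corrections → histogram → the configured per-well model
on every well, isolates per-well failures, and returns a tidy
:class:`PlateResult` ready for plate-level kinetic or equilibrium fits.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import bursts as bp
from . import corrections as corr
from . import mixtures as mx
from .exceptions import ConfigurationError, LayoutError
from .photons import PhotonStream

__all__ = [
    "PLATE_GEOMETRIES",
    "load_plate_layout",
    "run_plate_analysis",
    "qc_burst_rate_trend",
    "PlateResult",
]

#: rows x columns of the supported plate geometries
PLATE_GEOMETRIES = {48: (6, 8), 96: (8, 12), 384: (16, 24)}


def _valid_well_ids(geometry: int):
    rows, cols = PLATE_GEOMETRIES[geometry]
    return {f"{chr(ord('A') + r)}{c + 1:02d}"
            for r in range(rows) for c in range(cols)}


def load_plate_layout(path, geometry: int = 96) -> pd.DataFrame:
    """Read and validate a plate layout CSV.

    Well ids must be unique and well-formed for the declared geometry;
    unknown columns are preserved as condition variables.
    """
    if geometry not in PLATE_GEOMETRIES:
        raise LayoutError(f"unsupported geometry {geometry}; "
                          f"choose from {sorted(PLATE_GEOMETRIES)}")
    layout = pd.read_csv(path)
    if "well_id" not in layout.columns:
        raise LayoutError("layout CSV must have a well_id column")
    layout["well_id"] = layout["well_id"].astype(str).str.strip()
    dup = layout.loc[layout["well_id"].duplicated(), "well_id"]
    if len(dup):
        raise LayoutError(f"duplicate well id(s): {sorted(set(dup))}")
    valid = _valid_well_ids(geometry)
    bad = sorted(set(layout["well_id"]) - valid)
    if bad:
        raise LayoutError(
            f"well id(s) {bad} not valid for a {geometry}-well plate")
    layout.attrs["geometry"] = geometry
    return layout


@dataclass
class PlateResult:
    """Tidy result of a plate run.

    ``per_well`` has one row per layout well (failed or empty wells are
    flagged, never dropped); ``fits`` holds per-well model objects keyed by
    well id; ``provenance`` records the pipeline parameters and seed.
    """

    per_well: pd.DataFrame
    fits: dict = field(default_factory=dict)
    histograms: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def histogram_matrix(self) -> pd.DataFrame:
        """Wells × bins count matrix (for 2-D E-vs-condition maps)."""
        rows = {}
        for wid, h in self.histograms.items():
            rows[wid] = h.counts
        if not rows:
            return pd.DataFrame()
        any_h = next(iter(self.histograms.values()))
        return pd.DataFrame.from_dict(
            rows, orient="index",
            columns=[f"{c:.3f}" for c in any_h.centers]).sort_index()


DEFAULT_PIPELINE = {
    "burst_search": {"window": 500e-6, "min_rate_photons": 10,
                     "min_total_photons": 50},
    "background_method": "out_of_burst",
    "filter": None,                      # or kwargs for bursts.filter_bursts
    "corrections": None,                 # CorrectionSet, "derive", or None
    "histogram_bins": 50,
    "model": None,                       # None | "static-2g" | "dynamic-3g"
    "fraction_threshold": None,          # E threshold for f(E > thr)
    # plate-level fit across wells, e.g. {"kind": "lem",
    # "condition": "GdmCl_M"} or {"kind": "hairpin", "condition": "NaCl_M"}
    # or {"kind": "dose_response", "condition": "drug_M", ...kwargs}
    "plate_fit": None,
}


def _plate_level_fit(per_well: pd.DataFrame, spec: dict):
    from . import equilibrium as eq
    from . import kinetics as kin

    kind = spec["kind"]
    cond = spec["condition"]
    kwargs = {k: v for k, v in spec.items() if k not in ("kind", "condition")}
    ok = per_well.loc[~per_well["empty"].astype(bool)]
    if kind == "lem":
        tab = ok.rename(columns={cond: "denaturant_M",
                                 "f_above": "f_unfolded",
                                 "sd_f_above": "sd_f_unfolded"})
        return eq.fit_lem(tab, **kwargs)
    if kind == "dose_response":
        tab = ok.rename(columns={cond: "drug_M", "f_above": "f_folded",
                                 "sd_f_above": "sd_f_folded"})
        return eq.fit_dose_response(tab, **kwargs)
    if kind == "hairpin":
        tab = ok.rename(columns={cond: "salt_M",
                                 "k_open_per_ms": "k_open",
                                 "k_close_per_ms": "k_close"})
        return kin.fit_hairpin_salt_dependence(tab, **kwargs)
    raise ConfigurationError(f"unknown plate fit kind: {kind!r}")


def _load_streams(data) -> dict:
    if isinstance(data, dict):
        out = {}
        for wid, v in data.items():
            out[str(wid)] = v[0] if isinstance(v, tuple) else v
        return out
    data = Path(data)
    out = {}
    for p in sorted(data.glob("*.h5")):
        s = PhotonStream.from_hdf5(p)
        out[s.well_id or p.stem] = s
    return out


def run_plate_analysis(layout: pd.DataFrame, data, pipeline: dict | None = None,
                       seed: int = 0) -> PlateResult:
    """Run the per-well analysis chain across a plate.

    ``data`` is either ``{well_id: PhotonStream}`` (tuples from the
    simulator are accepted) or a directory of Photon-HDF5-style files.
    Wells are processed in sorted well-id order, so results do not depend on
    the order streams are supplied.  Per-well failures are isolated: the
    well row is flagged via ``error`` and the remaining wells proceed.
    """
    cfg = dict(DEFAULT_PIPELINE)
    if pipeline:
        cfg.update(pipeline)
    streams = _load_streams(data)
    cond_cols = [c for c in layout.columns if c != "well_id"]

    correction_set = cfg["corrections"]
    if isinstance(correction_set, str) and correction_set == "derive":
        tables = []
        for wid in sorted(streams):
            s = streams[wid]
            bg = bp.estimate_background(s, method=cfg["background_method"])
            tables.append(bp.find_bursts(s, background_rates=bg,
                                         **cfg["burst_search"]))
        correction_set = corr.derive_correction_set(pd.concat(
            tables, ignore_index=True))

    rows, fits, hists = [], {}, {}
    edges = mx.default_edges(cfg["histogram_bins"])
    for _, lrow in layout.sort_values("well_id").iterrows():
        wid = str(lrow["well_id"])
        row = {"well_id": wid}
        row.update({c: lrow[c] for c in cond_cols})
        stream = streams.get(wid)
        if stream is None:
            row.update({"n_bursts": 0, "empty": True, "error": ""})
            rows.append(row)
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                bg = bp.estimate_background(stream,
                                            method=cfg["background_method"])
                table = bp.find_bursts(stream, background_rates=bg,
                                       **cfg["burst_search"])
                if cfg["filter"]:
                    table = bp.filter_bursts(table, **cfg["filter"])
                if correction_set is not None:
                    table = corr.apply_correction_set(table, correction_set)
                hist = mx.build_histogram(table, edges, well_id=wid)
                hists[wid] = hist
                row["n_bursts"] = int(len(table))
                row["mean_duration_s"] = (float(table["duration"].mean())
                                          if len(table) else np.nan)
                row["duration_s"] = stream.duration
                row["empty"] = len(table) == 0
                row["error"] = ""
                if cfg["fraction_threshold"] is not None and len(table):
                    f, sd = mx.fraction_above_threshold(
                        table, cfg["fraction_threshold"])
                    row["f_above"], row["sd_f_above"] = f, sd
                if cfg["model"] == "static-2g" and len(table):
                    fit = mx.fit_static_mixture(hist, 2)
                    fits[wid] = fit
                    for i, c in fit.components.iterrows():
                        row[f"e_mean_{i}"] = c["mean"]
                        row[f"amp_{i}"] = c["amplitude"]
                    row["chi2_reduced"] = fit.chi2_reduced
                elif cfg["model"] == "dynamic-3g" and len(table):
                    fit = mx.fit_dynamic_three_gaussian(
                        hist, row["mean_duration_s"],
                        **cfg.get("dynamic_kwargs", {}))
                    fits[wid] = fit
                    row["k_open_per_ms"] = fit.k_open
                    row["k_close_per_ms"] = fit.k_close
                    row["chi2_reduced"] = fit.chi2_reduced
        except Exception as exc:
            row.setdefault("n_bursts", 0)
            row["empty"] = True
            row["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(row)

    per_well = pd.DataFrame(rows)
    plate_fit = None
    if cfg.get("plate_fit"):
        try:
            plate_fit = _plate_level_fit(per_well, cfg["plate_fit"])
        except Exception as exc:
            warnings.warn(f"plate-level fit failed: {exc}")
    if per_well.empty or per_well.get("n_bursts") is None or \
            int(per_well.get("n_bursts", pd.Series(dtype=int)).sum()) == 0:
        warnings.warn("plate analysis produced no bursts")
    failed = per_well.loc[per_well.get("error", "") != ""] \
        if "error" in per_well.columns else pd.DataFrame()
    provenance = {"pipeline": {k: (v if not hasattr(v, "__dict__") else str(v))
                               for k, v in cfg.items()},
                  "seed": seed,
                  "n_wells": int(len(layout)),
                  "n_failed": int(len(failed))}
    if plate_fit is not None:
        fits["__plate__"] = plate_fit
    return PlateResult(per_well=per_well, fits=fits, histograms=hists,
                       provenance=provenance)


def qc_burst_rate_trend(result: PlateResult, acquisition_order=None,
                        significance: float = 0.05):
    """Molecule-loss QC: regress bursts/min against acquisition order.

    Default acquisition order is row-major well-id order (A01→H12).  Returns
    a dict with the slope (bursts/min per well position), its 68% CI and
    two-sided p-value, and ``loss_flag`` set when the slope is significantly
    negative at the stated level.
    """
    pw = result.per_well
    usable = pw.loc[(pw.get("n_bursts", 0) > 0) &
                    pw.get("duration_s", pd.Series(dtype=float)).notna()]
    if len(usable) < 10:
        raise ConfigurationError("need at least 10 wells with bursts for QC")
    if acquisition_order is None:
        usable = usable.sort_values("well_id")
        order = np.arange(len(usable), dtype=float)
    else:
        pos = {w: i for i, w in enumerate(acquisition_order)}
        usable = usable.loc[usable["well_id"].isin(pos)]
        order = usable["well_id"].map(pos).to_numpy(float)
    rate = (usable["n_bursts"] / (usable["duration_s"] / 60.0)).to_numpy(float)
    fit = stats.linregress(order, rate)
    flag = bool(fit.slope < 0 and fit.pvalue < significance)
    return {
        "slope_bursts_per_min_per_well": float(fit.slope),
        "slope_stderr": float(fit.stderr),
        "p_value": float(fit.pvalue),
        "significance": significance,
        "loss_flag": flag,
        "n_wells": int(len(usable)),
    }
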