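"""Chemical interpretation of spectra and resolved components.

Covers four layers of interpretation:

* univariate biomolecular band ratios per cell (nucleic acid / protein /
  chain / unsaturation bands, each against the CH2/CH3 lipid band);
* rule-based annotation of resolved components (autofluorescence,
  nucleic-acid+protein, protein, lipids — lipids ranked by ester-band
  prominence then unsaturation);
* relative-abundance marker statistics between cell groups (Welch t);
* the unsaturation-index calibration: the C=C (1658 cm^-1) over CH2
  (1445 cm^-1) band ratio is linear in the number of C=C double bonds
  (NDB), which lets a resolved lipid be assigned an unsaturation index,
  with the 1745 cm^-1 ester C=O band separating glycerides from free
  fatty acids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats

from .errors import (
    InvalidModelError,
    MissingLabelError,
    ParameterError,
    ValidationError,
)
from .io import HyperspectralDataset, Spectrum

__all__ = [
    "Band",
    "BandLibrary",
    "DEFAULT_BANDS",
    "integrate_band",
    "band_intensity",
    "biomolecular_ratios",
    "ComponentAnnotation",
    "annotate_components",
    "marker_ratio_report",
    "CalibrationModel",
    "fit_unsaturation_calibration",
    "predict_double_bonds",
]


@dataclass(frozen=True)
class Band:
    name: str
    center: float       # cm^-1
    half_width: float   # integration half-width, cm^-1

    def __post_init__(self) -> None:
        if not (370.0 <= self.center <= 1800.0):
            raise ValidationError(f"band {self.name}: center outside 370-1800 cm^-1")
        if self.half_width <= 0:
            raise ValidationError(f"band {self.name}: half-width must be > 0")

    @property
    def window(self) -> tuple[float, float]:
        return (self.center - self.half_width, self.center + self.half_width)


_DEFAULT_HW = 15.0

#: named fingerprint bands used throughout the analysis
DEFAULT_BANDS = {
    b.name: b
    for b in [
        Band("amideI_CC", 1657.0, _DEFAULT_HW),   # amide I / C=C stretch
        Band("CH2CH3_def", 1446.0, _DEFAULT_HW),  # CH2/CH3 deformation (lipid)
        Band("CH2_twist", 1300.0, _DEFAULT_HW),
        Band("eq_CH", 1263.0, _DEFAULT_HW),       # =C-H in-plane bend
        Band("Phe", 1003.0, _DEFAULT_HW),         # phenylalanine ring breathing
        Band("CC_str", 879.0, _DEFAULT_HW),
        Band("OPO_nucleic", 786.0, _DEFAULT_HW),  # O-P-O nucleic backbone
        Band("nucleic_1576", 1576.0, _DEFAULT_HW),
        Band("ester_CO", 1745.0, _DEFAULT_HW),    # glyceride C=O stretch
        Band("unsat_num", 1658.0, _DEFAULT_HW),   # C=C stretch (numerator)
        Band("unsat_den", 1445.0, _DEFAULT_HW),   # CH2 deformation (denominator)
    ]
}

BandLibrary = dict  # name -> Band


def _axis_values(spec) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(spec, Spectrum):
        return spec.wavenumbers, spec.intensities
    axis, vals = spec
    return np.asarray(axis, dtype=float), np.asarray(vals, dtype=float)


def integrate_band(spec, band: Band, baseline_mode: str = "linear") -> float:
    """Trapezoidal band area over ``band.window``.

    With ``baseline_mode='linear'`` a straight line through the window
    endpoints is subtracted first (local background correction); 'none'
    integrates the raw signal.
    """
    axis, vals = _axis_values(spec)
    lo, hi = band.window
    if lo < axis[0] or hi > axis[-1]:
        raise ParameterError(
            f"band window [{lo}, {hi}] lies outside axis [{axis[0]}, {axis[-1]}]"
        )
    mask = (axis >= lo) & (axis <= hi)
    x, y = axis[mask], vals[mask]
    if x.size < 2:
        raise ParameterError(f"band window [{lo}, {hi}] covers < 2 samples")
    if baseline_mode == "linear":
        base = y[0] + (y[-1] - y[0]) * (x - x[0]) / (x[-1] - x[0])
        y = y - base
    elif baseline_mode != "none":
        raise ParameterError("baseline_mode must be 'linear' or 'none'")
    return float(np.trapezoid(y, x))


def band_intensity(spec, band: Band, baseline_mode: str = "linear") -> float:
    """Peak-height alternative to :func:`integrate_band` (max of the
    baseline-corrected window)."""
    axis, vals = _axis_values(spec)
    lo, hi = band.window
    if lo < axis[0] or hi > axis[-1]:
        raise ParameterError("band window outside axis")
    mask = (axis >= lo) & (axis <= hi)
    x, y = axis[mask], vals[mask]
    if baseline_mode == "linear":
        y = y - (y[0] + (y[-1] - y[0]) * (x - x[0]) / (x[-1] - x[0]))
    return float(np.max(y))


# ------------------------------------------------------- univariate ratios

#: Fig-1B-style ratios: each marker band against the CH2/CH3 lipid band
RATIO_DEFS = {
    "nucleic/lipid": ("OPO_nucleic", "CH2CH3_def"),
    "protein/lipid": ("Phe", "CH2CH3_def"),
    "CC_str/lipid": ("CC_str", "CH2CH3_def"),
    "eq_CH/lipid": ("eq_CH", "CH2CH3_def"),
}


def biomolecular_ratios(
    ds: HyperspectralDataset,
    bands: BandLibrary | None = None,
    baseline_mode: str = "linear",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell univariate band ratios plus per-group summaries.

    Returns ``(per_cell, summary)``: per-cell ratio table (zero-denominator
    cells flagged excluded) and group mean / SD / Welch-t p-value per ratio.
    """
    lib = bands or DEFAULT_BANDS
    rows = []
    for j in range(ds.n_spectra):
        spec = (ds.axis, ds.A[:, j])
        areas = {
            name: integrate_band(spec, lib[name], baseline_mode)
            for name in {b for pair in RATIO_DEFS.values() for b in pair}
        }
        row = {
            "cell_id": ds.columns["cell_id"].iloc[j],
            "group": ds.columns["group"].iloc[j],
            "excluded": False,
        }
        for rname, (num, den) in RATIO_DEFS.items():
            if areas[den] == 0:
                row[rname] = np.nan
                row["excluded"] = True
            else:
                row[rname] = areas[num] / areas[den]
        rows.append(row)
    per_cell = pd.DataFrame(rows)

    summaries = []
    groups = pd.unique(per_cell["group"])
    for rname in RATIO_DEFS:
        entry = {"ratio": rname}
        by_group = {}
        for g in groups:
            vals = per_cell.loc[
                (per_cell["group"] == g) & ~per_cell["excluded"], rname
            ].to_numpy()
            entry[f"mean_{g}"] = float(np.mean(vals)) if vals.size else np.nan
            entry[f"sd_{g}"] = float(np.std(vals, ddof=1)) if vals.size > 1 else np.nan
            by_group[g] = vals
        if len(groups) == 2 and all(v.size > 1 for v in by_group.values()):
            a, b = (by_group[g] for g in groups)
            entry["p_welch"] = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        else:
            entry["p_welch"] = np.nan
        summaries.append(entry)
    return per_cell, pd.DataFrame(summaries)


# ------------------------------------------------------- component annotation


@dataclass
class ComponentAnnotation:
    index: int
    label: str                      # "AF", "AF+P", "N+P", "Lipid 1", ..., "P", "unassigned"
    family: str                     # "AF", "AF+P", "N+P", "Lipid", "P", "unassigned"
    peaks: dict = field(default_factory=dict)   # band name -> prominence
    background_fraction: float = 0.0
    ester: bool = False
    unsaturation_ratio: float = float("nan")


def _peak_prominences(
    w: np.ndarray,
    axis: np.ndarray,
    rel_floor: float = 0.2,
    match_tol: float = 8.0,
) -> dict:
    """Map band name -> prominence for significant peaks near library
    band centers.

    Peak presence = a local maximum whose prominence is at least
    ``rel_floor`` x the largest prominence in the spectrum, located
    within ``match_tol`` cm^-1 of the band center.  The relative floor
    rejects the small crosstalk peaks that curve resolution leaves on
    otherwise sparse component spectra.
    """
    idx, props = signal.find_peaks(w, prominence=1e-12)
    if idx.size == 0:
        return {}
    proms = props["prominences"]
    thr = rel_floor * float(proms.max())
    keep = proms >= thr
    idx, proms = idx[keep], proms[keep]
    found = {}
    for name, band in DEFAULT_BANDS.items():
        near = np.abs(axis[idx] - band.center) <= match_tol
        if np.any(near):
            found[name] = float(proms[near].max())
    return found


def _peak_above(
    w: np.ndarray, axis: np.ndarray, center: float, threshold: float, match_tol: float = 8.0
) -> bool:
    """Is there a local maximum near ``center`` with absolute prominence
    >= ``threshold``?  Used for peaks riding the autofluorescence
    envelope, where a relative floor is meaningless."""
    idx, props = signal.find_peaks(w, prominence=threshold)
    return bool(np.any(np.abs(axis[idx] - center) <= match_tol))


def _background_fraction(w: np.ndarray, axis: np.ndarray, window_cm: float = 150.0) -> float:
    """Fraction of total intensity under a running-minimum baseline —
    high for broad autofluorescence envelopes, low for sparse band systems."""
    step = float(np.median(np.diff(axis)))
    half = max(1, int(round(window_cm / (2 * step))))
    n = w.size
    baseline = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        baseline[i] = w[lo:hi].min()
    tot = float(np.sum(np.abs(w)))
    return float(np.sum(baseline) / tot) if tot > 0 else 1.0


def _unsat_ratio(w: np.ndarray, axis: np.ndarray, baseline_mode: str = "linear") -> float:
    try:
        den = integrate_band((axis, w), DEFAULT_BANDS["unsat_den"], baseline_mode)
        num = integrate_band((axis, w), DEFAULT_BANDS["unsat_num"], baseline_mode)
    except ParameterError:
        return float("nan")
    return num / den if den != 0 else float("nan")


#: bands whose joint prominence breaks ties between duplicate labels
_REQUIRED_BANDS = {
    "N+P": ("OPO_nucleic", "nucleic_1576", "Phe"),
    "P": ("Phe", "CC_str", "amideI_CC"),
}


def annotate_components(
    W: np.ndarray,
    axis: np.ndarray,
    rel_floor: float = 0.2,
    af_peak_frac: float = 0.08,
    background_threshold: float = 0.35,
    prominence_factor: float | None = None,
) -> list[ComponentAnnotation]:
    """Rule-based chemical labels for resolved spectral components.

    * peaks at 786 AND 1576 AND 1003 -> "N+P" (nucleic acid + protein);
    * peaks at 1263 AND 1300 AND 1440-1446 AND 1657 without 786 -> lipid;
    * 1003 AND 1657 AND 879, no nucleic bands, no strong 1300 (below
      half the 1003 prominence) -> "P";
    * dominant smooth envelope (background fraction >= threshold): "AF",
      or "AF+P" when protein peaks at 1003 / ~1450 / 1657 rise at least
      ``af_peak_frac`` x the maximum intensity above the envelope;
    * featureless otherwise -> "AF"; anything else -> "unassigned".

    Peak presence uses a prominence floor relative to the spectrum's
    largest peak (``rel_floor``), which tolerates curve-resolution
    crosstalk; if two components claim "N+P" or "P" the one with the
    larger summed prominence of the required bands keeps the label.
    Lipids are numbered "Lipid 1..q" by descending 1745 cm^-1 ester-band
    prominence, ties broken by descending unsaturation ratio — so a
    glyceride outranks free fatty acids.

    ``prominence_factor`` is accepted for backward compatibility and
    interpreted as a rel_floor override when given as a fraction < 1.
    """
    if prominence_factor is not None and prominence_factor < 1.0:
        rel_floor = prominence_factor
    W = np.asarray(W, dtype=float)
    axis = np.asarray(axis, dtype=float)
    out: list[ComponentAnnotation] = []
    for j in range(W.shape[1]):
        w = W[:, j]
        peaks = _peak_prominences(w, axis, rel_floor)
        bg = _background_fraction(w, axis)
        ester = "ester_CO" in peaks
        unsat = _unsat_ratio(w, axis)

        has = peaks.__contains__
        strong_1300 = peaks.get("CH2_twist", 0.0) >= 0.5 * peaks.get("Phe", np.inf)
        # nucleic-acid evidence needs both backbone (786) and base (1576)
        # bands — a single band at the detection floor is crosstalk
        nucleic = has("OPO_nucleic") and has("nucleic_1576")

        if nucleic and has("Phe"):
            family = "N+P"
        elif (
            has("eq_CH")
            and has("CH2_twist")
            and (has("CH2CH3_def") or has("unsat_den"))
            and has("amideI_CC")
            and not nucleic
        ):
            family = "Lipid"
        elif (
            has("Phe")
            and has("amideI_CC")
            and has("CC_str")
            and not nucleic
            and not strong_1300
        ):
            family = "P"
        elif bg >= background_threshold:
            thr = af_peak_frac * float(w.max())
            protein_on_envelope = (
                _peak_above(w, axis, 1003.0, thr)
                and _peak_above(w, axis, 1657.0, thr)
                and (_peak_above(w, axis, 1450.0, thr) or _peak_above(w, axis, 1446.0, thr))
            )
            family = "AF+P" if protein_on_envelope else "AF"
        elif not peaks:
            family = "AF"
        else:
            family = "unassigned"
        out.append(
            ComponentAnnotation(
                index=j,
                label=family,
                family=family,
                peaks=peaks,
                background_fraction=bg,
                ester=ester,
                unsaturation_ratio=unsat,
            )
        )

    for fam, bands in _REQUIRED_BANDS.items():
        claimants = [a for a in out if a.family == fam]
        if len(claimants) > 1:
            claimants.sort(key=lambda a: -sum(a.peaks.get(b, 0.0) for b in bands))
            for a in claimants[1:]:
                a.label = a.family = "unassigned"

    lipids = [a for a in out if a.family == "Lipid"]
    lipids.sort(
        key=lambda a: (
            -a.peaks.get("ester_CO", 0.0),
            -(a.unsaturation_ratio if np.isfinite(a.unsaturation_ratio) else -np.inf),
        )
    )
    for rank, a in enumerate(lipids, start=1):
        a.label = f"Lipid {rank}"
    return out


# ------------------------------------------------------- marker ratio report


def _numerically_zero(row: np.ndarray, zero_tol: float) -> np.ndarray:
    """Abundances the solver effectively set to zero: exact zeros plus
    values below ``zero_tol`` x the median positive abundance (projected
    ALS shrinks vanished components to tiny residuals rather than clean
    zeros)."""
    row = np.asarray(row, dtype=float)
    pos = row[row > 0]
    floor = zero_tol * float(np.median(pos)) if pos.size else 0.0
    return row <= floor


def marker_ratio_report(
    H: np.ndarray,
    annotations: list[ComponentAnnotation],
    groups,
    zero_tol: float = 0.01,
) -> dict:
    """Fig-5-style relative-abundance statistics for resolved components.

    For every lipid against N+P, against P, and against each other lipid:
    per-cell abundance ratios, group mean +/- standard error, Welch-t
    p-value, plus log10 abundance pairs for scatter plots.  Cells whose
    denominator abundance is (numerically) zero are excluded and counted.
    """
    H = np.asarray(H, dtype=float)
    groups = np.asarray(groups)
    by_label: dict[str, int] = {}
    for a in annotations:
        if a.label not in by_label:  # first occurrence wins
            by_label[a.label] = a.index
    lipid_labels = sorted(
        (lab for lab in by_label if lab.startswith("Lipid")),
        key=lambda s: int(s.split()[1]),
    )
    for required in ("N+P", "P"):
        if required not in by_label:
            raise MissingLabelError(f"no component annotated {required!r}")
    if not lipid_labels:
        raise MissingLabelError("no component annotated as a lipid")

    pairs = []
    for lip in lipid_labels:
        pairs.append((lip, "N+P"))
    for lip in lipid_labels:
        pairs.append((lip, "P"))
    for i in range(len(lipid_labels)):
        for j in range(i + 1, len(lipid_labels)):
            pairs.append((lipid_labels[i], lipid_labels[j]))

    uniq = pd.unique(groups)
    report: dict = {"ratios": {}, "scatter": {}, "group_order": list(uniq)}
    for num_lab, den_lab in pairs:
        num = H[by_label[num_lab], :]
        den = H[by_label[den_lab], :]
        excluded = _numerically_zero(den, zero_tol)
        ratio = np.full(H.shape[1], np.nan)
        ratio[~excluded] = num[~excluded] / den[~excluded]
        entry = {"n_excluded": int(excluded.sum()), "per_group": {}}
        samples = []
        for g in uniq:
            vals = ratio[(groups == g) & ~excluded]
            entry["per_group"][str(g)] = {
                "mean": float(np.mean(vals)) if vals.size else float("nan"),
                "sem": float(stats.sem(vals)) if vals.size > 1 else float("nan"),
                "n": int(vals.size),
            }
            samples.append(vals)
        if len(uniq) == 2 and all(v.size > 1 for v in samples):
            entry["p_welch"] = float(
                stats.ttest_ind(samples[0], samples[1], equal_var=False).pvalue
            )
        else:
            entry["p_welch"] = float("nan")
        report["ratios"][f"{num_lab}/{den_lab}"] = entry

        pos = ~_numerically_zero(num, zero_tol) & ~excluded
        report["scatter"][f"{num_lab} vs {den_lab}"] = pd.DataFrame(
            {
                "log10_x": np.log10(den[pos]),
                "log10_y": np.log10(num[pos]),
                "group": groups[pos],
            }
        )
        report["scatter"][f"{num_lab} vs {den_lab}"].attrs["n_omitted"] = int(
            (~pos).sum()
        )
    return report


# ------------------------------------------------------- unsaturation index


@dataclass
class CalibrationModel:
    """Linear map between the C=C/CH2 band ratio r and the number of
    double bonds: r = slope * NDB + intercept."""

    slope: float
    intercept: float
    r_squared: float
    residuals: np.ndarray
    standards: pd.DataFrame  # columns: name, ndb, ratio

    def predict_ratio(self, ndb: float) -> float:
        return self.slope * ndb + self.intercept

    def invert(self, ratio: float) -> float:
        if self.slope <= 0:
            raise InvalidModelError("calibration slope must be > 0 to invert")
        return (ratio - self.intercept) / self.slope


def _standard_ratio(spec, baseline_mode: str = "linear", mode: str = "area") -> float:
    """C=C (1658) over CH2 (1445) band ratio after 1445-area normalization.

    Normalizing by the 1445 band area and then taking the 1658 area is
    identical to the direct area ratio; both bands use the same local
    linear baseline.  ``mode='height'`` uses peak heights instead.
    """
    fn = integrate_band if mode == "area" else band_intensity
    den = fn(spec, DEFAULT_BANDS["unsat_den"], baseline_mode)
    if den == 0:
        raise ParameterError("CH2 (1445 cm^-1) band area is zero; cannot normalize")
    num = fn(spec, DEFAULT_BANDS["unsat_num"], baseline_mode)
    return num / den


def fit_unsaturation_calibration(
    standards,
    baseline_mode: str = "linear",
    mode: str = "area",
) -> CalibrationModel:
    """OLS fit of the 1658/1445 ratio against NDB over fatty-acid standards.

    ``standards`` is a sequence of ``(spectrum, ndb)`` or
    ``(name, spectrum, ndb)`` entries; at least two distinct NDB values
    are required.
    """
    rows = []
    for entry in standards:
        if len(entry) == 3:
            name, spec, ndb = entry
        else:
            spec, ndb = entry
            name = getattr(spec, "meta", {}).get("name", f"std{len(rows)}")
        rows.append({"name": name, "ndb": float(ndb), "ratio": _standard_ratio(spec, baseline_mode, mode)})
    table = pd.DataFrame(rows)
    if len(table) < 2:
        raise ParameterError("need at least 2 standards")
    if table["ndb"].nunique() < 2:
        raise InvalidModelError("all standards share one NDB value: singular fit")
    x = table["ndb"].to_numpy()
    y = table["ratio"].to_numpy()
    res = stats.linregress(x, y)
    fitted = res.slope * x + res.intercept
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return CalibrationModel(float(res.slope), float(res.intercept), r2, y - fitted, table)


@dataclass
class DoubleBondPrediction:
    ndb: float
    ndb_nearest: int
    ratio: float
    ester: bool


def predict_double_bonds(
    model: CalibrationModel,
    spec,
    baseline_mode: str = "linear",
    mode: str = "area",
    rel_floor: float = 0.2,
) -> DoubleBondPrediction:
    """Unsaturation index of a lipid spectrum via the inverse calibration,
    plus an ester flag from the 1745 cm^-1 C=O band (glyceride vs free
    fatty acid)."""
    if model.slope <= 0:
        raise InvalidModelError("calibration slope must be > 0")
    r = _standard_ratio(spec, baseline_mode, mode)
    ndb = model.invert(r)
    axis, vals = _axis_values(spec)
    peaks = _peak_prominences(vals, axis, rel_floor)
    return DoubleBondPrediction(
        ndb=float(ndb),
        ndb_nearest=int(round(ndb)),
        ratio=float(r),
        ester="ester_CO" in peaks,
    )
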