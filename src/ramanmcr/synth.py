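"""Ground-truthed synthetic single-cell Raman data.

Emulates the structure of a two-group single-cell Raman study: 30 cells
per group, 5 point spectra per cell, fingerprint axis 370-1800 cm^-1 at
1 cm^-1 steps.  Each point spectrum is a non-negative mixture of seven
pure components — two autofluorescence envelopes (one carrying protein
bands), a nucleic-acid+protein blend, three unsaturated lipids and a
protein — with Lorentzian band shapes (FWHM 12 cm^-1).

The abundance model has three levels:

* per-cell composition: lognormal around component base abundances
  (CV 0.25 across cells), with the cancer-like group scaled by effect
  multipliers (default: the di-unsaturated ester-bearing lipid x0.4, the
  nucleic-acid+protein component x1.3) — the ground-truth group
  difference the analysis should recover;
* droplet-free cells: each lipid is absent (abundance exactly zero) in a
  small fraction of cells, mirroring the zero abundances single-cell
  measurements show;
* per-point sampling: the 5 random points of a cell hit different
  subcellular structures, so each point re-draws a lognormal jitter
  whose CV is component-specific (large for the nucleus-localised
  nucleic component and for droplet-borne lipids, small for the diffuse
  autofluorescence).  This organelle-scale contrast is what makes the
  non-negative factorization identifiable, as it is for real cells.

Detector effects: additive Gaussian noise (sigma = 1% of the mean
signal) and occasional cosmic-ray spikes at recorded coordinates.
Lipid C=C (1658 cm^-1) band amplitudes are proportional to the number
of double bonds (NDB) against a constant CH2 (1445 cm^-1) band, so the
unsaturation-index calibration is linear by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import HyperspectralDataset, Spectrum

__all__ = [
    "GeneratorConfig",
    "StandardSpectrum",
    "SimulatedCells",
    "make_pure_components",
    "simulate_cells",
    "simulate_standards",
    "COMPONENT_NAMES",
]

COMPONENT_NAMES = ("AF+P", "AF", "N+P", "Lipid 1", "Lipid 2", "Lipid 3", "P")

#: C=C (1658 cm^-1) band amplitude per double bond, relative to the CH2
#: (1445 cm^-1) band amplitude of ~1 — shared by cell lipids and
#: fatty-acid standards so one calibration applies to both.
CC_AMPLITUDE_PER_NDB = 0.3

#: NDB and ester-band status of the lipid components
LIPID_TRUTH = {"Lipid 1": (2, True), "Lipid 2": (1, False), "Lipid 3": (1, False)}

#: mean abundance of each component (arbitrary units, before group effects)
BASE_ABUNDANCE = {
    "AF+P": 0.5,
    "AF": 0.4,
    "N+P": 0.6,
    "Lipid 1": 0.9,
    "Lipid 2": 0.4,
    "Lipid 3": 0.4,
    "P": 0.45,
}

#: within-cell point-to-point lognormal jitter CV per component
#: (organelle-scale sampling heterogeneity of "5 random points per cell")
POINT_JITTER_CV = {
    "AF+P": 0.5,
    "AF": 0.5,
    "N+P": 0.6,
    "Lipid 1": 0.25,
    "Lipid 2": 0.8,
    "Lipid 3": 0.9,
    "P": 0.35,
}


def _default_base():
    return dict(BASE_ABUNDANCE)


def _default_jitter():
    return dict(POINT_JITTER_CV)


@dataclass
class GeneratorConfig:
    """Stated world of the simulation; defaults mirror the study design
    (30 cells/group x 5 points, 370-1800 cm^-1, fingerprint band set)."""

    n_cells_per_group: int = 30
    points_per_cell: int = 5
    wn_min: float = 370.0
    wn_max: float = 1800.0
    wn_step: float = 1.0
    fwhm: float = 12.0                      # Lorentzian FWHM, cm^-1
    components: tuple = COMPONENT_NAMES     # a subset selects a smaller world
    groups: tuple = ("HMEpC-like", "MCF7-like")
    lipid1_effect: float = 0.4              # x on Lipid 1 in the cancer-like group
    np_effect: float = 1.3                  # x on N+P in the cancer-like group
    abundance_cv_cell: float = 0.25         # lognormal CV across cells
    point_jitter_cv: dict = field(default_factory=_default_jitter)
    base_abundance: dict = field(default_factory=_default_base)
    lipid_dropout: float = 0.02             # droplet-free cell probability per lipid
    noise_sigma: float = 0.01               # Gaussian sigma / mean signal level
    spike_rate: float = 0.1                 # cosmic-ray probability per spectrum
    spike_factor: float = 100.0             # spike amplitude / column median level
    background_amplitude: float = 0.0       # extra additive envelope (off: the
                                            # AF components carry the background)
    counts_scale: float = 1000.0            # detector counts per abundance unit
    seed: int = 0

    def axis(self) -> np.ndarray:
        n = int(round((self.wn_max - self.wn_min) / self.wn_step)) + 1
        return self.wn_min + self.wn_step * np.arange(n)


def _lorentz(x: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    g = fwhm / 2.0
    return g * g / ((x - center) ** 2 + g * g)


def _envelope(u: np.ndarray, coeffs) -> np.ndarray:
    """4th-order polynomial autofluorescence envelope, clipped at zero."""
    p = np.zeros_like(u)
    for power, c in enumerate(coeffs):
        p += c * u**power
    return np.maximum(p, 0.0)


# coefficients (a0..a4 in u = normalized wavenumber) of the two envelopes:
# AF falls off as (1-u)^4, AF+P is a broad mid-axis hump 16 u^2 (1-u)^2
_ENV_AF = (1.0, -4.0, 6.0, -4.0, 1.0)
_ENV_AFP = (0.0, 0.0, 16.0, -32.0, 16.0)

# band tables: (center cm^-1, amplitude); lipid C=C bands are added
# separately in proportion to NDB
_PROTEIN_BANDS = [(879.0, 0.45), (1003.0, 0.9), (1446.0, 0.5), (1657.0, 0.8)]
_AFP_BANDS = [(1003.0, 0.9), (1450.0, 0.7), (1657.0, 0.8)]
_NP_BANDS = [(786.0, 1.2), (1576.0, 0.9), (879.0, 0.3), (1003.0, 0.6), (1657.0, 0.7)]


def _lipid_bands(ndb: float, ester: bool, variant: int = 0) -> list:
    """Chain-band pattern per lipid.  The three lipids share the
    =C-H / CH2-twist / CH2-def fingerprint but differ in their chain C-C
    signatures (1080 vs 1130 cm^-1) and band weights, as distinct lipid
    species do."""
    if variant == 1:
        bands = [(1263.0, 0.35), (1300.0, 1.0), (1445.0, 0.95), (1080.0, 1.0)]
    elif variant == 2:
        bands = [(1263.0, 0.55), (1300.0, 0.55), (1445.0, 1.05), (1130.0, 1.0)]
    else:
        bands = [(1263.0, 0.45), (1300.0, 0.8), (1445.0, 1.0)]
    bands.append((1658.0, CC_AMPLITUDE_PER_NDB * ndb))
    if ester:
        bands.append((1745.0, 0.8))
    return bands


def _bands_to_spectrum(axis: np.ndarray, bands, fwhm: float) -> np.ndarray:
    y = np.zeros_like(axis)
    for center, amp in bands:
        y += amp * _lorentz(axis, center, fwhm)
    return y


def make_pure_components(config: GeneratorConfig | None = None) -> pd.DataFrame:
    """Unit-norm non-negative pure-component spectra (ground-truth W),
    indexed by wavenumber with one column per component."""
    cfg = config or GeneratorConfig()
    axis = cfg.axis()
    u = (axis - cfg.wn_min) / (cfg.wn_max - cfg.wn_min)
    fw = cfg.fwhm
    spectra = {}
    for name in cfg.components:
        if name == "AF":
            y = _envelope(u, _ENV_AF)
        elif name == "AF+P":
            y = _envelope(u, _ENV_AFP) + _bands_to_spectrum(axis, _AFP_BANDS, fw)
        elif name == "N+P":
            y = _bands_to_spectrum(axis, _NP_BANDS, fw)
        elif name == "P":
            y = _bands_to_spectrum(axis, _PROTEIN_BANDS, fw)
        elif name in LIPID_TRUTH:
            ndb, ester = LIPID_TRUTH[name]
            variant = {"Lipid 1": 0, "Lipid 2": 1, "Lipid 3": 2}[name]
            y = _bands_to_spectrum(axis, _lipid_bands(ndb, ester, variant), fw)
        else:
            raise ValueError(f"unknown component {name!r}")
        spectra[name] = y / np.linalg.norm(y)
    return pd.DataFrame(spectra, index=pd.Index(axis, name="wavenumber"))


@dataclass
class SimulatedCells:
    """A simulated study plus its ground truth."""

    dataset: HyperspectralDataset
    W_true: pd.DataFrame            # wavenumber-indexed pure spectra (unit norm)
    H_true: np.ndarray              # k x n abundances (counts scale included)
    component_names: tuple
    spikes: list = field(default_factory=list)  # (row, col) of injected spikes
    config: GeneratorConfig = None


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative lognormal noise with unit mean and given CV."""
    if cv <= 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def simulate_cells(config: GeneratorConfig | None = None) -> SimulatedCells:
    """Simulate the full study: A = W_true H_true (+ background) + noise,
    with spikes injected at recorded coordinates.  Deterministic given
    ``config.seed``."""
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    W_df = make_pure_components(cfg)
    axis = W_df.index.to_numpy()
    W = W_df.to_numpy()
    names = tuple(W_df.columns)
    k = len(names)
    n = 2 * cfg.n_cells_per_group * cfg.points_per_cell

    base = np.array([cfg.base_abundance[name] for name in names])
    effects = np.ones((2, k))
    for j, name in enumerate(names):
        if name == "Lipid 1":
            effects[1, j] = cfg.lipid1_effect
        elif name == "N+P":
            effects[1, j] = cfg.np_effect
    jitter_cv = np.array([cfg.point_jitter_cv.get(name, 0.1) for name in names])
    is_lipid = np.array([name in LIPID_TRUTH for name in names])

    H = np.empty((k, n))
    meta_rows = []
    col = 0
    for g_idx, group in enumerate(cfg.groups):
        for c in range(cfg.n_cells_per_group):
            cell_id = f"{group}_c{c:02d}"
            cell_ab = (
                base
                * effects[g_idx]
                * _lognormal_factor(rng, cfg.abundance_cv_cell, k)
            )
            # droplet-free cells: a lipid can be entirely absent
            drop = is_lipid & (rng.random(k) < cfg.lipid_dropout)
            cell_ab[drop] = 0.0
            for p in range(cfg.points_per_cell):
                jit = np.array(
                    [_lognormal_factor(rng, jitter_cv[j], 1)[0] for j in range(k)]
                )
                H[:, col] = cell_ab * jit * cfg.counts_scale
                meta_rows.append(
                    {
                        "id": f"{cell_id}_{p}",
                        "cell_id": cell_id,
                        "group": group,
                        "point": p,
                    }
                )
                col += 1

    A = W @ H
    if cfg.background_amplitude > 0:
        u = (axis - cfg.wn_min) / (cfg.wn_max - cfg.wn_min)
        env = _envelope(u, _ENV_AF)
        A = A + cfg.background_amplitude * env[:, None]
    if cfg.noise_sigma > 0:
        sigma = cfg.noise_sigma * float(A.mean())
        A = A + rng.normal(0.0, sigma, size=A.shape)

    spikes = []
    if cfg.spike_rate > 0:
        hit = rng.random(n) < cfg.spike_rate
        for j in np.nonzero(hit)[0]:
            i = int(rng.integers(1, A.shape[0] - 1))  # keep off the edges
            A[i, j] += cfg.spike_factor * float(np.median(np.abs(A[:, j])))
            spikes.append((i, int(j)))

    ds = HyperspectralDataset(axis, A, pd.DataFrame(meta_rows))
    return SimulatedCells(ds, W_df, H, names, spikes, cfg)


#: fatty-acid standards: (short name, number of C=C double bonds)
STANDARD_ACIDS = [
    ("PMA", 1),   # palmitoleic
    ("OA", 1),    # oleic
    ("LA", 2),    # linoleic
    ("ALA", 3),   # alpha-linolenic
    ("GLA", 3),   # gamma-linolenic
    ("AA", 4),    # arachidonic
    ("EPA", 5),   # eicosapentaenoic
    ("DHA", 6),   # docosahexaenoic
]


@dataclass
class StandardSpectrum:
    name: str
    ndb: int
    ester: bool
    spectrum: Spectrum


def simulate_standards(config: GeneratorConfig | None = None) -> list[StandardSpectrum]:
    """Noiseless fatty-acid standard spectra (eight free acids, NDB 1-6)
    plus trilinolein (TLA: the linoleate triglyceride, NDB 2 with the
    1745 cm^-1 ester band).  The 1658 band amplitude is proportional to
    NDB against a constant 1445 band, so the calibration ratio is an
    exactly linear function of NDB."""
    cfg = config or GeneratorConfig()
    axis = cfg.axis()
    chain = [(1263.0, 0.45), (1300.0, 0.8), (1445.0, 1.0), (1080.0, 0.5)]
    out = []
    for name, ndb in STANDARD_ACIDS + [("TLA", 2)]:
        ester = name == "TLA"
        bands = chain + [(1658.0, CC_AMPLITUDE_PER_NDB * ndb)]
        if ester:
            bands = bands + [(1745.0, 0.8)]
        y = _bands_to_spectrum(axis, bands, cfg.fwhm)
        spec = Spectrum(axis, y, {"name": name, "ndb": ndb, "ester": ester})
        out.append(StandardSpectrum(name, ndb, ester, spec))
    return out
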