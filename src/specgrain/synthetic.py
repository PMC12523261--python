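"""Synthetic NIR spectra with content-coupled absorption bands.

The real study data (per-sample mean near-infrared spectra of rice seeds with
wet-chemistry prolamin and glutelin contents) are not publicly released, so
this module generates datasets with the same statistical structure: 200-band
spectra on a 980–1684 nm grid, protein contents drawn from truncated normal
distributions matching the published summary statistics, and Gaussian
absorption features in the N–H / O–H overtone regions whose amplitude scales
linearly with the analyte content (a Beer–Lambert-like mixing model).

Every downstream stage — outlier screening, wavelength selection, calibration
models, saliency interpretation — is exercised against these datasets, whose
planted band centers provide a recoverable ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, ParseError

ANALYTES = ("prolamin", "glutelin")

__all__ = [
    "ANALYTES",
    "WavelengthGrid",
    "SpectraSet",
    "ContentTable",
    "ContentParams",
    "Band",
    "GeneratorConfig",
    "generate_dataset",
    "read_spectra",
    "write_spectra",
    "read_contents",
    "write_contents",
    "load_generator_config",
]


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing wavelength axis in nm."""

    wavelengths: np.ndarray

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        if wl.ndim != 1 or wl.size < 1:
            raise ConfigError("grid.wavelengths: need a nonempty 1-D axis")
        if not np.all(np.diff(wl) > 0):
            raise ConfigError("grid.wavelengths: must be strictly increasing")
        object.__setattr__(self, "wavelengths", wl)

    @classmethod
    def linspace(cls, n_bands: int, start_nm: float, end_nm: float) -> "WavelengthGrid":
        if n_bands < 2:
            raise ConfigError("grid.n_bands: must be >= 2")
        if not start_nm < end_nm:
            raise ConfigError("grid.start_nm/end_nm: require start < end")
        return cls(np.linspace(start_nm, end_nm, n_bands))

    def __len__(self) -> int:
        return len(self.wavelengths)

    def nearest_index(self, nm: float) -> int:
        return int(np.argmin(np.abs(self.wavelengths - nm)))


@dataclass(frozen=True)
class SpectraSet:
    """Sample x wavelength absorbance-like matrix plus its grid and sample ids."""

    values: np.ndarray
    grid: WavelengthGrid
    sample_ids: tuple

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ConfigError("spectra values must be a 2-D matrix")
        if v.shape[1] != len(self.grid):
            raise ConfigError(
                f"spectra have {v.shape[1]} bands but the grid has {len(self.grid)}"
            )
        if not np.all(np.isfinite(v)):
            raise ConfigError("spectra values must all be finite")
        ids = tuple(str(s) for s in self.sample_ids)
        if len(ids) != v.shape[0]:
            raise ConfigError("sample_ids length must match the number of rows")
        if len(set(ids)) != len(ids):
            raise ConfigError("sample_ids must be unique")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "sample_ids", ids)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_bands(self) -> int:
        return self.values.shape[1]

    def take_samples(self, idx) -> "SpectraSet":
        idx = np.asarray(idx, dtype=int)
        return SpectraSet(self.values[idx], self.grid,
                          tuple(self.sample_ids[i] for i in idx))

    def take_bands(self, idx) -> "SpectraSet":
        idx = np.asarray(idx, dtype=int)
        return SpectraSet(self.values[:, idx],
                          WavelengthGrid(self.grid.wavelengths[idx]),
                          self.sample_ids)


@dataclass(frozen=True)
class ContentTable:
    """Per-sample prolamin and glutelin contents (% mass fraction of flour)."""

    sample_ids: tuple
    prolamin: np.ndarray
    glutelin: np.ndarray

    def __post_init__(self):
        ids = tuple(str(s) for s in self.sample_ids)
        pro = np.asarray(self.prolamin, dtype=float)
        glu = np.asarray(self.glutelin, dtype=float)
        if pro.shape != (len(ids),) or glu.shape != (len(ids),):
            raise ConfigError("content arrays must be 1-D and match sample_ids")
        if np.any(pro < 0) or np.any(glu < 0):
            raise ConfigError("contents must be nonnegative")
        if len(set(ids)) != len(ids):
            raise ConfigError("sample_ids must be unique")
        object.__setattr__(self, "sample_ids", ids)
        object.__setattr__(self, "prolamin", pro)
        object.__setattr__(self, "glutelin", glu)

    def values(self, analyte: str) -> np.ndarray:
        if analyte not in ANALYTES:
            raise ConfigError(f"analyte must be one of {ANALYTES}, got {analyte!r}")
        return getattr(self, analyte)

    def take(self, idx) -> "ContentTable":
        idx = np.asarray(idx, dtype=int)
        return ContentTable(tuple(self.sample_ids[i] for i in idx),
                            self.prolamin[idx], self.glutelin[idx])

    def __len__(self) -> int:
        return len(self.sample_ids)


@dataclass(frozen=True)
class ContentParams:
    """Truncated-normal parameters for one analyte (%, mass fraction)."""

    mean: float
    sd: float
    min: float
    max: float

    def validate(self, name: str) -> None:
        if not self.sd > 0:
            raise ConfigError(f"content_params[{name}].sd: must be > 0")
        if not (self.min < self.mean < self.max):
            raise ConfigError(
                f"content_params[{name}]: require min < mean < max "
                f"(got {self.min}, {self.mean}, {self.max})"
            )


@dataclass(frozen=True)
class Band:
    """A Gaussian absorption feature: center/width in nm, per-analyte coupling.

    ``coupling`` maps analyte name -> absorbance per % content at the band
    center; a band may couple to both analytes (shared chemical bond).
    """

    center_nm: float
    width_nm: float
    coupling: dict

    def profile(self, wavelengths: np.ndarray) -> np.ndarray:
        return np.exp(-0.5 * ((wavelengths - self.center_nm) / self.width_nm) ** 2)


# Published summary statistics of the 192-sample training set; the generator's
# default content distributions.
TABLE1_TRAINING = {
    "prolamin": ContentParams(mean=0.70, sd=0.07, min=0.51, max=0.88),
    "glutelin": ContentParams(mean=5.01, sd=0.99, min=3.43, max=7.38),
}

# Default band library. Centers sit in the NIR assignment windows for protein:
# 1000–1100 nm (second N–H overtones), 1450–1550 nm (first N–H overtones),
# with a shared O–H feature near 1450 nm. Couplings are scaled so that, at
# typical contents (prolamin ~0.7 %, glutelin ~5 %), each analyte contributes
# a few tenths of an absorbance unit.
DEFAULT_BANDS = (
    Band(1020.0, 25.0, {"prolamin": 0.50}),
    Band(1500.0, 35.0, {"prolamin": 0.40}),
    Band(1050.0, 25.0, {"glutelin": 0.08}),
    Band(1480.0, 35.0, {"glutelin": 0.06}),
    Band(1450.0, 40.0, {"prolamin": 0.25, "glutelin": 0.04}),
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Everything needed to generate one spectra/content dataset.

    Defaults emulate the study conditions: 200 bands on 980–1684 nm, content
    distributions from the published training-set statistics, mild linear
    baseline and instrument noise typical of NIR absorbance measurements.
    """

    n_samples: int = 288
    seed: int = 0
    n_bands: int = 200
    start_nm: float = 980.0
    end_nm: float = 1684.0
    content_params: dict = field(default_factory=lambda: dict(TABLE1_TRAINING))
    content_correlation: float = 0.3
    band_library: tuple = DEFAULT_BANDS
    baseline_offset: float = 0.20
    baseline_slope: float = 1e-4  # absorbance per nm
    noise_sd: float = 0.005      # absorbance units

    def validate(self) -> None:
        if self.n_samples < 6:
            raise ConfigError("n_samples: must be >= 6 so a 4:1:1 split is nonempty")
        if not -1 < self.content_correlation < 1:
            raise ConfigError("content_correlation: must lie in (-1, 1)")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd: must be >= 0")
        grid = self.grid()  # validates n_bands / start / end
        for name in ANALYTES:
            if name not in self.content_params:
                raise ConfigError(f"content_params: missing analyte {name!r}")
            params = self.content_params[name]
            if not isinstance(params, ContentParams):
                params = ContentParams(**params)
            params.validate(name)
        lo, hi = grid.wavelengths[0], grid.wavelengths[-1]
        for band in self.band_library:
            if not (lo <= band.center_nm <= hi):
                raise ConfigError(
                    f"band_library: center {band.center_nm} nm outside grid "
                    f"[{lo}, {hi}] nm"
                )
            if not band.width_nm > 0:
                raise ConfigError("band_library: width_nm must be > 0")

    def grid(self) -> WavelengthGrid:
        return WavelengthGrid.linspace(self.n_bands, self.start_nm, self.end_nm)

    def params(self, analyte: str) -> ContentParams:
        p = self.content_params[analyte]
        return p if isinstance(p, ContentParams) else ContentParams(**p)

    def planted_centers(self, analyte: str) -> list:
        """Band (center, width) pairs coupled to the given analyte."""
        return [(b.center_nm, b.width_nm) for b in self.band_library
                if b.coupling.get(analyte, 0.0) != 0.0]

    def with_(self, **kwargs) -> "GeneratorConfig":
        return replace(self, **kwargs)


def _draw_contents(config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    """Correlated truncated-normal contents by pairwise rejection sampling."""
    rho = config.content_correlation
    cov = np.array([[1.0, rho], [rho, 1.0]])
    chol = np.linalg.cholesky(cov)
    params = [config.params(a) for a in ANALYTES]
    out = np.empty((config.n_samples, 2))
    filled = 0
    while filled < config.n_samples:
        z = rng.standard_normal((max(64, config.n_samples), 2)) @ chol.T
        x = np.column_stack([p.mean + p.sd * z[:, j] for j, p in enumerate(params)])
        ok = np.all([(x[:, j] >= p.min) & (x[:, j] <= p.max)
                     for j, p in enumerate(params)], axis=0)
        accepted = x[ok]
        take = min(len(accepted), config.n_samples - filled)
        out[filled:filled + take] = accepted[:take]
        filled += take
    return out


def generate_dataset(config: GeneratorConfig) -> tuple:
    """Generate a seeded (SpectraSet, ContentTable) pair.

    Contents follow truncated normals with the configured moments and bounds;
    each spectrum is ``baseline + sum_analytes content * sum_bands
    coupling * Gaussian(center, width) + N(0, noise_sd)``. Identical configs
    (including seed) give bit-identical outputs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    grid = config.grid()
    wl = grid.wavelengths

    contents = _draw_contents(config, rng)

    baseline = config.baseline_offset + config.baseline_slope * (wl - wl[0])
    signatures = np.zeros((2, len(wl)))
    for band in config.band_library:
        prof = band.profile(wl)
        for j, analyte in enumerate(ANALYTES):
            coeff = band.coupling.get(analyte, 0.0)
            if coeff:
                signatures[j] += coeff * prof

    spectra = baseline[None, :] + contents @ signatures
    if config.noise_sd > 0:
        spectra = spectra + rng.normal(0.0, config.noise_sd, spectra.shape)

    ids = tuple(f"S{i + 1:04d}" for i in range(config.n_samples))
    return (SpectraSet(spectra, grid, ids),
            ContentTable(ids, contents[:, 0], contents[:, 1]))


# ---------------------------------------------------------------------------
# Delimited-text I/O.  Spectra: first column sample_id, header of wavelengths
# in nm.  Contents: columns sample_id, prolamin, glutelin.
# ---------------------------------------------------------------------------

def write_spectra(spectra: SpectraSet, path) -> None:
    df = pd.DataFrame(spectra.values,
                      index=list(spectra.sample_ids),
                      columns=[repr(float(w)) for w in spectra.grid.wavelengths])
    df.index.name = "sample_id"
    df.to_csv(path, float_format=None)


def read_spectra(path) -> SpectraSet:
    try:
        df = pd.read_csv(path, index_col=0, dtype=str)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    try:
        wl = np.array([float(c) for c in df.columns])
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric wavelength header: {exc}") from exc
    if not np.all(np.diff(wl) > 0):
        raise ParseError(f"{path}: header wavelengths must be strictly increasing")
    ids = [str(i) for i in df.index]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ParseError(f"{path}: duplicate sample ids {dupes}")
    values = np.empty(df.shape, dtype=float)
    for r in range(df.shape[0]):
        row = df.iloc[r].to_numpy()
        try:
            values[r] = row.astype(float)
        except (TypeError, ValueError) as exc:
            # +2: one for the header line, one for 1-based numbering
            raise ParseError(f"{path}: non-numeric value at data row {r + 1} "
                             f"(file line {r + 2}): {exc}") from exc
        if np.any(pd.isna(values[r])):
            raise ParseError(f"{path}: missing value at data row {r + 1} "
                             f"(file line {r + 2})")
    return SpectraSet(values, WavelengthGrid(wl), tuple(ids))


def write_contents(contents: ContentTable, path) -> None:
    df = pd.DataFrame({
        "sample_id": list(contents.sample_ids),
        "prolamin": [repr(float(v)) for v in contents.prolamin],
        "glutelin": [repr(float(v)) for v in contents.glutelin],
    })
    df.to_csv(path, index=False)


def read_contents(path) -> ContentTable:
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    for col in ("sample_id", "prolamin", "glutelin"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    ids = [str(i) for i in df["sample_id"]]
    if len(set(ids)) != len(ids):
        raise ParseError(f"{path}: duplicate sample ids")
    arrays = {}
    for col in ("prolamin", "glutelin"):
        vals = np.empty(len(df))
        for r, cell in enumerate(df[col]):
            try:
                vals[r] = float(cell)
            except (TypeError, ValueError) as exc:
                raise ParseError(f"{path}: non-numeric {col} at data row {r + 1} "
                                 f"(file line {r + 2})") from exc
        arrays[col] = vals
    return ContentTable(tuple(ids), arrays["prolamin"], arrays["glutelin"])


def load_generator_config(path) -> GeneratorConfig:
    """Load a GeneratorConfig from a YAML or JSON document."""
    with open(path) as fh:
        text = fh.read()
    doc = yaml.safe_load(text) if not str(path).endswith(".json") else json.loads(text)
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: expected a mapping at top level")
    if "content_params" in doc:
        doc["content_params"] = {
            k: ContentParams(**v) if isinstance(v, dict) else v
            for k, v in doc["content_params"].items()
        }
    if "band_library" in doc:
        doc["band_library"] = tuple(
            Band(**b) if isinstance(b, dict) else b for b in doc["band_library"]
        )
    try:
        config = GeneratorConfig(**doc)
    except TypeError as exc:
        raise ConfigError(f"{path}: {exc}") from exc
    config.validate()
    return config
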