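"""1D spectrum container and readers/writers for tabular and JCAMP-DX files.

Spectra are stored as (ppm, intensity) pairs with the spectrometer frequency
carried along so coupling offsets specified in Hz can be mapped onto the ppm
axis.  Chemical shifts are referenced to TSP: 0 ppm for ¹H, −2.0 ppm for
¹³C.  The JCAMP-DX support covers plain (AFFN, fixed-point) ``##XYDATA=
(X++(Y..Y))`` blocks — the uncompressed flavor used for exchanging 1D
processed spectra.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import numpy.typing as npt
import yaml

from ..errors import FitError

__all__ = ["Spectrum1D", "read_spectrum", "write_spectrum", "read_jcamp", "write_jcamp"]

VALID_NUCLEI = ("1H", "13C")
#: TSP reference position per nucleus (ppm).
TSP_REFERENCE_PPM = {"1H": 0.0, "13C": -2.0}
REFERENCE_NAMES = {"1H": "TSP_1H_0ppm", "13C": "TSP_13C_minus2ppm"}


@dataclass(frozen=True)
class Spectrum1D:
    """A processed 1D NMR spectrum on a ppm axis.

    Parameters
    ----------
    nucleus
        "1H" or "13C".
    ppm
        Strictly monotone chemical-shift axis.
    intensity
        Real intensities, same length as ``ppm``.
    spectrometer_freq_MHz
        Larmor frequency of the observed nucleus; the Hz-per-ppm factor.
    reference
        Name of the chemical-shift reference convention.
    """

    nucleus: str
    ppm: npt.NDArray[np.float64]
    intensity: npt.NDArray[np.float64]
    spectrometer_freq_MHz: float
    reference: str = ""

    def __post_init__(self) -> None:
        if self.nucleus not in VALID_NUCLEI:
            raise ValueError(f"nucleus must be one of {VALID_NUCLEI}, got {self.nucleus!r}")
        ppm = np.asarray(self.ppm, dtype=float)
        intensity = np.asarray(self.intensity, dtype=float)
        if ppm.ndim != 1 or ppm.shape != intensity.shape:
            raise ValueError("ppm and intensity must be 1-D arrays of equal length")
        diffs = np.diff(ppm)
        if not ((diffs > 0).all() or (diffs < 0).all()):
            raise ValueError("ppm axis must be strictly monotone")
        if self.spectrometer_freq_MHz <= 0:
            raise ValueError("spectrometer_freq_MHz must be positive")
        ref = self.reference or REFERENCE_NAMES[self.nucleus]
        if ref != REFERENCE_NAMES[self.nucleus]:
            raise ValueError(
                f"reference {ref!r} inconsistent with nucleus {self.nucleus}; "
                f"expected {REFERENCE_NAMES[self.nucleus]!r}"
            )
        object.__setattr__(self, "ppm", ppm)
        object.__setattr__(self, "intensity", intensity)
        object.__setattr__(self, "reference", ref)

    @property
    def hz_per_ppm(self) -> float:
        return self.spectrometer_freq_MHz

    def window(self, ppm_lo: float, ppm_hi: float) -> "Spectrum1D":
        """Extract the sub-spectrum with ppm in [ppm_lo, ppm_hi]."""
        if ppm_lo >= ppm_hi:
            raise ValueError("ppm_lo must be < ppm_hi")
        mask = (self.ppm >= ppm_lo) & (self.ppm <= ppm_hi)
        if mask.sum() < 8:
            raise FitError(
                f"window [{ppm_lo}, {ppm_hi}] ppm absent from spectrum "
                f"({self.ppm.min():.2f}..{self.ppm.max():.2f} ppm)"
            )
        return replace(self, ppm=self.ppm[mask], intensity=self.intensity[mask])

    def noise_sigma(self) -> float:
        """Noise estimate from the 20% of points smallest in |intensity|.

        The 0.2-quantile of |x| for zero-mean Gaussian noise is 0.2533 sigma,
        so dividing the quantile by that factor recovers sigma while staying
        insensitive to peaks (which occupy the large-|x| tail).
        """
        q = float(np.quantile(np.abs(self.intensity), 0.2))
        return max(q / 0.2533, 1e-300)


def _sidecar_path(path: Path) -> Path | None:
    for suffix in (".yaml", ".yml", ".json"):
        cand = path.with_suffix(path.suffix + suffix)
        if cand.exists():
            return cand
    return None


def _load_sidecar(path: Path) -> dict:
    text = path.read_text()
    if path.suffix == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def read_spectrum(path: str | Path, **metadata) -> Spectrum1D:
    """Read a spectrum from a two-column tabular file or a JCAMP-DX file.

    Tabular files are whitespace- or comma-separated (ppm, intensity) pairs;
    required metadata (nucleus, spectrometer_freq_MHz) come from keyword
    arguments or from a ``<file>.yaml``/``.json`` sidecar.
    """
    path = Path(path)
    if path.suffix.lower() in (".jdx", ".dx", ".jcamp"):
        return read_jcamp(path, **metadata)
    sidecar = _sidecar_path(path)
    meta = _load_sidecar(sidecar) if sidecar else {}
    meta.update(metadata)
    if "nucleus" not in meta or "spectrometer_freq_MHz" not in meta:
        raise ValueError(
            f"tabular spectrum {path} needs nucleus and spectrometer_freq_MHz "
            "from a metadata sidecar or keyword arguments"
        )
    raw = np.loadtxt(path, delimiter="," if "," in path.read_text(encoding="utf-8")[:200] else None)
    if raw.ndim != 2 or raw.shape[1] < 2:
        raise ValueError(f"{path} is not a two-column (ppm, intensity) table")
    return Spectrum1D(
        nucleus=str(meta["nucleus"]),
        ppm=raw[:, 0],
        intensity=raw[:, 1],
        spectrometer_freq_MHz=float(meta["spectrometer_freq_MHz"]),
        reference=str(meta.get("reference", "")),
    )


def write_spectrum(spec: Spectrum1D, path: str | Path, sidecar: bool = True) -> Path:
    """Write a spectrum as a two-column table plus a YAML metadata sidecar."""
    path = Path(path)
    np.savetxt(path, np.column_stack([spec.ppm, spec.intensity]), fmt="%.8g")
    if sidecar:
        meta = {
            "nucleus": spec.nucleus,
            "spectrometer_freq_MHz": spec.spectrometer_freq_MHz,
            "reference": spec.reference,
        }
        path.with_suffix(path.suffix + ".yaml").write_text(yaml.safe_dump(meta))
    return path


def read_jcamp(path: str | Path, **metadata) -> Spectrum1D:
    """Read an AFFN (fixed-point) ``##XYDATA=(X++(Y..Y))`` JCAMP-DX file."""
    path = Path(path)
    header: dict[str, str] = {}
    x: list[float] = []
    y: list[float] = []
    in_xy = False
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("##"):
            key, _, value = line[2:].partition("=")
            key = key.strip().upper().replace(" ", "")
            if key == "XYDATA":
                in_xy = True
                continue
            if key == "END":
                in_xy = False
            header[key] = value.strip()
            continue
        if in_xy:
            vals = [float(tok) for tok in line.replace(",", " ").split()]
            if len(vals) < 2:
                continue
            x0, ys = vals[0], vals[1:]
            x.extend([x0 + i for i in range(len(ys))])  # index placeholder, rescaled below
            y.extend(ys)
    if not y:
        raise ValueError(f"{path}: no XYDATA block found")
    firstx = float(header.get("FIRSTX", x[0]))
    lastx = float(header.get("LASTX", x[-1]))
    npoints = int(float(header.get("NPOINTS", len(y))))
    if npoints != len(y):
        raise ValueError(f"{path}: NPOINTS={npoints} but {len(y)} ordinates read")
    xfactor = float(header.get("XFACTOR", 1.0))
    yfactor = float(header.get("YFACTOR", 1.0))
    ppm = np.linspace(firstx * xfactor, lastx * xfactor, npoints)
    intensity = np.asarray(y, dtype=float) * yfactor
    freq = metadata.get("spectrometer_freq_MHz") or float(header.get(".OBSERVEFREQUENCY", 0) or 0)
    nucleus = metadata.get("nucleus") or header.get(".OBSERVENUCLEUS", "").strip("^")
    if nucleus not in VALID_NUCLEI or not freq:
        raise ValueError(
            f"{path}: nucleus/frequency not found in JCAMP header; pass "
            "nucleus= and spectrometer_freq_MHz= explicitly"
        )
    return Spectrum1D(
        nucleus=nucleus,
        ppm=ppm,
        intensity=intensity,
        spectrometer_freq_MHz=float(freq),
        reference=str(metadata.get("reference", "")),
    )


def write_jcamp(spec: Spectrum1D, path: str | Path, title: str = "citrace spectrum") -> Path:
    """Write an AFFN ``##XYDATA=(X++(Y..Y))`` JCAMP-DX file (one pair per line)."""
    path = Path(path)
    lines = [
        f"##TITLE={title}",
        "##JCAMP-DX=4.24",
        "##DATA TYPE=NMR SPECTRUM",
        f"##.OBSERVE NUCLEUS=^{spec.nucleus}",
        f"##.OBSERVE FREQUENCY={spec.spectrometer_freq_MHz}",
        "##XUNITS=PPM",
        "##YUNITS=ARBITRARY UNITS",
        "##XFACTOR=1.0",
        "##YFACTOR=1.0",
        f"##FIRSTX={spec.ppm[0]:.8g}",
        f"##LASTX={spec.ppm[-1]:.8g}",
        f"##NPOINTS={spec.ppm.size}",
        "##XYDATA=(X++(Y..Y))",
    ]
    lines += [f"{p:.6f} {v:.8g}" for p, v in zip(spec.ppm, spec.intensity)]
    lines.append("##END=")
    path.write_text("\n".join(lines) + "\n")
    return path
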