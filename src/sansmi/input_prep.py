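"""Select <q> points from an experimental curve and emit a run configuration.

The workflow mirrors how biased-run inputs are prepared in practice: pick a
modest number of experimental points between qmin and qmax (optionally
adding extra points where the curve has features), attach the per-point
resolution sigma1 and the uncertainty-bound heuristic
(SIGMA_MAX = 8% of the experimental intensity, SIGMA_MIN = 25% and
DSIGMA = 4% of SIGMA_MAX) and write everything as one keyword block.

The emitted block deliberately reuses the QVALUE/EXPINT/SIGMARES/SIGMA_*
keyword names for traceability; it is this package's own configuration
format, not input for any other engine.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io_model import ExperimentalCurve, FormatError
from .metainference import sigma_defaults

__all__ = ["QSelection", "select_qvalues", "emit_config", "parse_config"]


@dataclass
class QSelection:
    """Selected experimental points plus derived per-point MC bounds."""

    q: np.ndarray
    intensity: np.ndarray
    sigma_res: np.ndarray | None
    sigma_min: np.ndarray
    sigma_max: np.ndarray
    dsigma: np.ndarray
    indices: np.ndarray | None = None  # into the source curve, when known

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        n = self.q.size
        if n < 1:
            raise ValueError("selection must contain at least one point")
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("selected q must be unique and sorted")

    @property
    def n_points(self) -> int:
        return self.q.size

    def curve(self) -> ExperimentalCurve:
        return ExperimentalCurve(q=self.q, intensity=self.intensity,
                                 sigma_res=self.sigma_res)


def select_qvalues(curve: ExperimentalCurve, qmin: float, qmax: float,
                   npoints: int, extra_q=None,
                   log_spaced: bool = False) -> QSelection:
    """Pick the experimental points nearest to evenly spaced targets.

    Targets are linear in q by default (``log_spaced`` switches to
    log-spaced targets); duplicate nearest hits collapse to one point.
    ``extra_q`` values are mapped to their nearest experimental points and
    appended, so selected q are always members of the experimental grid.
    """
    if qmin >= qmax:
        raise ValueError("qmin must be smaller than qmax")
    if npoints < 2:
        raise ValueError("npoints must be >= 2")
    if qmin < curve.q[0] or qmax > curve.q[-1]:
        raise ValueError(
            f"requested range [{qmin}, {qmax}] outside the experimental grid "
            f"[{curve.q[0]}, {curve.q[-1]}]"
        )
    if log_spaced:
        targets = np.geomspace(qmin, qmax, npoints)
    else:
        targets = np.linspace(qmin, qmax, npoints)
    if extra_q is not None:
        targets = np.concatenate([targets, np.asarray(extra_q, dtype=float)])
    idx = np.unique([int(np.argmin(np.abs(curve.q - t))) for t in targets])
    sel = curve.subset(idx)
    sigma_max, sigma_min, dsigma = sigma_defaults(sel.intensity)
    return QSelection(q=sel.q, intensity=sel.intensity,
                      sigma_res=sel.sigma_res, sigma_min=sigma_min,
                      sigma_max=sigma_max, dsigma=dsigma, indices=idx)


def _fmt(x: float) -> str:
    return f"{float(x):.10g}"


def emit_config(selection: QSelection, n_quad: int = 10,
                scatlen_file: str = "scatlens.plumed", atoms: str = "solute",
                bias_stride: int = 100, no_smear: bool = False) -> str:
    """Render the run-configuration keyword block as a string.

    Per selected point: QVALUE, EXPINT, SIGMARES (omitted with
    ``no_smear``, which also forces N to 1) and the SIGMA_MIN/SIGMA_MAX/
    DSIGMA heuristics.  Emission -> parse -> emission is a fixed point.
    """
    if np.any(selection.intensity <= 0):
        raise ValueError("experimental intensities must be positive")
    smear = not no_smear
    if smear and selection.sigma_res is None:
        raise ValueError(
            "selection has no resolution sigma1; pass no_smear=True to "
            "emit a configuration without smearing"
        )
    lines = ["# sansmi run configuration"]
    lines.append(f"N={1 if no_smear else n_quad}")
    lines.append(f"SCATLENFILE={scatlen_file}")
    lines.append(f"ATOMS={atoms}")
    lines.append(f"BIAS_STRIDE={bias_stride}")
    for i in range(selection.n_points):
        k = i + 1
        lines.append(f"QVALUE{k}={_fmt(selection.q[i])}")
        lines.append(f"EXPINT{k}={_fmt(selection.intensity[i])}")
        if smear:
            lines.append(f"SIGMARES{k}={_fmt(selection.sigma_res[i])}")
        lines.append(f"SIGMA_MIN{k}={_fmt(selection.sigma_min[i])}")
        lines.append(f"SIGMA_MAX{k}={_fmt(selection.sigma_max[i])}")
        lines.append(f"DSIGMA{k}={_fmt(selection.dsigma[i])}")
    return "\n".join(lines) + "\n"


def parse_config(source: str | Path) -> tuple[QSelection, dict]:
    """Parse a configuration block (path or literal text).

    Returns the QSelection and an options dict with the scalar keys
    (N, SCATLENFILE, ATOMS, BIAS_STRIDE).
    """
    text = source
    if isinstance(source, Path) or (
        isinstance(source, str) and "\n" not in source and Path(source).exists()
    ):
        text = Path(source).read_text()
    options: dict = {}
    per_point: dict[str, dict[int, float]] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        if "=" not in stripped:
            raise FormatError(f"line {lineno}: expected KEY=value, got "
                              f"{stripped!r}")
        key, value = stripped.split("=", 1)
        key = key.strip()
        value = value.strip()
        matched = False
        for base in ("QVALUE", "EXPINT", "SIGMARES", "SIGMA_MIN",
                     "SIGMA_MAX", "DSIGMA"):
            if key.startswith(base) and key[len(base):].isdigit():
                per_point.setdefault(base, {})[int(key[len(base):])] = float(value)
                matched = True
                break
        if matched:
            continue
        if key in ("N", "BIAS_STRIDE"):
            options[key] = int(value)
        else:
            options[key] = value
    if "QVALUE" not in per_point:
        raise FormatError("configuration contains no QVALUE entries")

    def collect(base: str) -> np.ndarray | None:
        if base not in per_point:
            return None
        d = per_point[base]
        ks = sorted(d)
        if ks != list(range(1, len(ks) + 1)):
            raise FormatError(f"{base} indices are not contiguous from 1")
        return np.array([d[k] for k in ks])

    q = collect("QVALUE")
    intensity = collect("EXPINT")
    sigma_res = collect("SIGMARES")
    sigma_min = collect("SIGMA_MIN")
    sigma_max = collect("SIGMA_MAX")
    dsigma = collect("DSIGMA")
    if intensity is None or intensity.size != q.size:
        raise FormatError("EXPINT entries must match QVALUE entries")
    if sigma_max is None:
        sigma_max, sigma_min, dsigma = sigma_defaults(intensity)
    selection = QSelection(q=q, intensity=intensity, sigma_res=sigma_res,
                           sigma_min=sigma_min, sigma_max=sigma_max,
                           dsigma=dsigma)
    return selection, options
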