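"""Tracer preparation: δ-notation conversion, preservation/lipid corrections,
and fatty-acid profile handling.

Stable isotope ratios are reported in δ notation, the per-mil deviation of a
sample's heavy/light isotope ratio from an international standard (VPDB for
carbon, atmospheric N₂ for nitrogen).  Skin samples preserved in DMSO or
lipid-extracted before combustion carry systematic offsets that must be
removed before mixing analysis; the correction coefficients are tissue- and
study-specific and are therefore *configuration inputs*, not constants.

Fatty acids are expressed as mass percent of total FAs using the C:DnX
shorthand (C carbon atoms, D double bonds, nX position of the double bond
closest to the terminal methyl group).  Diet inference uses only the
"extended dietary" subset — FAs deposited in predator tissue largely
unmodified from diet.
"""

from __future__ import annotations

import math
import warnings
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "TracerError",
    "CorrectionError",
    "IsotopeMeasurement",
    "LinearCorrection",
    "CorrectionModel",
    "FAProfile",
    "ratio_to_delta",
    "delta_to_ratio",
    "apply_corrections",
    "apply_corrections_table",
    "select_fa_subset",
    "essential_fa_sum",
    "extended_dietary_subset",
    "ESSENTIAL_FAS",
]

#: FAs whose sum is tracked as the "major essential FA" body-condition proxy.
ESSENTIAL_FAS = ("20:5n3", "22:6n3", "20:4n6")


class TracerError(ValueError):
    """Invalid tracer value or operation."""


class CorrectionError(TracerError):
    """A correction was mis-applied (e.g. applied twice to the same sample)."""


def ratio_to_delta(r_sample: float, r_standard: float) -> float:
    """Convert an isotope abundance ratio to δ notation (‰).

    δX = (R_sample / R_standard − 1) × 1000, with R the heavy/light isotope
    abundance ratio of the sample and of the international standard.
    """
    if r_standard <= 0:
        raise TracerError(f"standard ratio must be positive, got {r_standard!r}")
    if r_sample < 0:
        raise TracerError(f"sample ratio must be non-negative, got {r_sample!r}")
    return (r_sample / r_standard - 1.0) * 1000.0


def delta_to_ratio(delta: float, r_standard: float) -> float:
    """Inverse of :func:`ratio_to_delta`: recover R_sample from a δ value."""
    if r_standard <= 0:
        raise TracerError(f"standard ratio must be positive, got {r_standard!r}")
    return (delta / 1000.0 + 1.0) * r_standard


@dataclass(frozen=True)
class IsotopeMeasurement:
    """One tissue sample's tracer values plus handling metadata.

    Parameters
    ----------
    d13c, d15n:
        δ13C (vs VPDB) and δ15N (vs atmospheric N₂), in ‰.
    cn_ratio:
        Mass C:N ratio of the analysed tissue, if measured.
    lipid_extracted:
        Whether lipids were chemically removed before combustion (affects δ15N).
    preservation:
        ``"frozen"`` or ``"DMSO"``.
    corrections_applied:
        Names of correction effects already applied; guards idempotence.
    """

    d13c: float
    d15n: float
    cn_ratio: float | None = None
    lipid_extracted: bool = False
    preservation: str = "frozen"
    corrections_applied: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (math.isfinite(self.d13c) and math.isfinite(self.d15n)):
            raise TracerError("δ values must be finite")
        if self.cn_ratio is not None and not self.cn_ratio > 0:
            raise TracerError(f"C:N ratio must be positive, got {self.cn_ratio!r}")
        if self.preservation not in ("frozen", "DMSO"):
            raise TracerError(f"unknown preservation {self.preservation!r}")


@dataclass(frozen=True)
class LinearCorrection:
    """Per-tracer linear correction: corrected = slope · raw + offset.

    The additive (offset-only) case is the default; a slope ≠ 1 expresses a
    regression-based correction.
    """

    offset: float = 0.0
    slope: float = 1.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.offset) and math.isfinite(self.slope)):
            raise TracerError("correction coefficients must be finite")

    def __call__(self, value: float) -> float:
        return self.slope * value + self.offset

    @property
    def is_identity(self) -> bool:
        return self.offset == 0.0 and self.slope == 1.0


_EFFECTS = ("lipid", "dmso")


@dataclass(frozen=True)
class CorrectionModel:
    """Corrections for lipid extraction (δ15N) and DMSO preservation (both tracers).

    Coefficients are supplied per effect and per tracer (``"d13c"``/``"d15n"``).
    The same fish-derived lipid correction is conventionally reused for
    zooplankton, whose C:N ratios are comparable.
    """

    lipid: Mapping[str, LinearCorrection] = field(default_factory=dict)
    dmso: Mapping[str, LinearCorrection] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for effect in _EFFECTS:
            for tracer in getattr(self, effect):
                if tracer not in ("d13c", "d15n"):
                    raise TracerError(f"unknown tracer {tracer!r} in {effect} correction")

    @classmethod
    def from_dict(cls, cfg: Mapping) -> "CorrectionModel":
        """Build from a config mapping, e.g.

        ``{"lipid": {"d15n": {"offset": 0.3}}, "dmso": {"d13c": {"offset": -0.4}}}``
        """
        kwargs = {}
        for effect in _EFFECTS:
            block = cfg.get(effect, {}) or {}
            kwargs[effect] = {
                tracer: LinearCorrection(**dict(coeffs)) for tracer, coeffs in block.items()
            }
        return cls(**kwargs)

    @classmethod
    def null(cls, warn: bool = True) -> "CorrectionModel":
        """All-zero offsets.  Warns loudly: study-specific coefficients should
        be supplied via configuration whenever available."""
        if warn:
            warnings.warn(
                "Using a null correction model (zero offsets). Lipid-extraction and "
                "DMSO corrections are tissue- and study-specific; supply coefficients "
                "via the `corrections:` config block.",
                stacklevel=2,
            )
        return cls()

    def applicable_effects(self, sample: IsotopeMeasurement) -> list[str]:
        out = []
        if sample.lipid_extracted and self.lipid:
            out.append("lipid")
        if sample.preservation == "DMSO" and self.dmso:
            out.append("dmso")
        return out


def apply_corrections(
    sample: IsotopeMeasurement, model: CorrectionModel
) -> tuple[IsotopeMeasurement, dict[str, str]]:
    """Apply every applicable correction effect exactly once.

    Returns the corrected copy and a per-effect report mapping each effect in
    the model to ``"applied"`` or ``"not applicable"``.  Re-applying an effect
    already recorded in ``sample.corrections_applied`` raises
    :class:`CorrectionError` (idempotence guard).
    """
    report: dict[str, str] = {}
    d13c, d15n = sample.d13c, sample.d15n
    fired: list[str] = []
    applicable = model.applicable_effects(sample)
    for effect in _EFFECTS:
        coeffs = getattr(model, effect)
        if not coeffs:
            continue
        if effect not in applicable:
            report[effect] = "not applicable"
            continue
        if effect in sample.corrections_applied:
            raise CorrectionError(
                f"{effect} correction already applied to this sample (idempotence guard)"
            )
        if "d13c" in coeffs:
            d13c = coeffs["d13c"](d13c)
        if "d15n" in coeffs:
            d15n = coeffs["d15n"](d15n)
        fired.append(effect)
        report[effect] = "applied"
    corrected = replace(
        sample,
        d13c=d13c,
        d15n=d15n,
        corrections_applied=sample.corrections_applied + tuple(fired),
    )
    return corrected, report


def apply_corrections_table(df: pd.DataFrame, model: CorrectionModel) -> tuple[pd.DataFrame, dict]:
    """Vectorised :func:`apply_corrections` over a consumer/prey table.

    Expects columns ``d13C``/``d15N`` and optionally ``preservation`` and
    ``lipid_extracted``; absent metadata columns default to frozen /
    not-extracted (so no correction fires).  Returns the corrected copy and a
    count of rows touched per effect.
    """
    out = df.copy()
    counts = {}
    masks = {
        "lipid": out["lipid_extracted"].astype(bool)
        if "lipid_extracted" in out
        else pd.Series(False, index=out.index),
        "dmso": out["preservation"].eq("DMSO")
        if "preservation" in out
        else pd.Series(False, index=out.index),
    }
    col = {"d13c": "d13C", "d15n": "d15N"}
    for effect in _EFFECTS:
        coeffs = getattr(model, effect)
        mask = masks[effect]
        if not coeffs or not mask.any():
            counts[effect] = 0
            continue
        for tracer, corr in coeffs.items():
            out.loc[mask, col[tracer]] = corr.slope * out.loc[mask, col[tracer]] + corr.offset
        counts[effect] = int(mask.sum())
    return out, counts


class FAProfile(Mapping):
    """A fatty-acid composition in mass percent of total FAs.

    Behaves as a read-only mapping FA-name → mass percent.  Values must be
    non-negative and sum to 100 (within 1e-6) unless ``normalize=True``, in
    which case the input is closed to 100 first.
    """

    #: number of FAs zero-filled by the last subset selection that built this profile
    zero_filled: int

    def __init__(self, values: Mapping[str, float], normalize: bool = False):
        vals = {str(k): float(v) for k, v in values.items()}
        if not vals:
            raise TracerError("empty FA profile")
        arr = np.array(list(vals.values()))
        if (arr < 0).any():
            bad = [k for k, v in vals.items() if v < 0]
            raise TracerError(f"negative FA mass percent for {bad}")
        total = arr.sum()
        if normalize:
            if total <= 0:
                raise TracerError("cannot normalize an all-zero FA profile")
            vals = {k: v * 100.0 / total for k, v in vals.items()}
        elif abs(total - 100.0) > 1e-6:
            raise TracerError(
                f"FA profile sums to {total!r}, not 100; pass normalize=True to close"
            )
        self._data = vals
        self.zero_filled = 0

    def __getitem__(self, key: str) -> float:
        return self._data[key]

    def __iter__(self):
        return iter(self._data)

    def __len__(self) -> int:
        return len(self._data)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"FAProfile({len(self)} FAs, total={sum(self._data.values()):.6f})"

    @classmethod
    def from_series(cls, s: pd.Series, normalize: bool = False) -> "FAProfile":
        return cls(s.to_dict(), normalize=normalize)

    def as_series(self) -> pd.Series:
        return pd.Series(self._data, dtype=float)


def select_fa_subset(profile: FAProfile, subset: Iterable[str]) -> FAProfile:
    """Restrict a profile to ``subset`` and renormalise to 100 mass percent.

    FAs named in the subset but absent from the profile contribute 0 and are
    counted in ``result.zero_filled`` (with a warning); within-subset relative
    proportions are preserved by the renormalisation.
    """
    subset = list(dict.fromkeys(subset))
    if not subset:
        raise TracerError("FA subset must be non-empty")
    restricted = {name: profile.get(name, 0.0) for name in subset}
    missing = sum(1 for name in subset if name not in profile)
    if sum(restricted.values()) <= 0:
        raise TracerError("subset selects an all-zero restriction of the profile")
    if missing:
        warnings.warn(f"{missing} FA(s) in subset absent from profile; zero-filled", stacklevel=2)
    out = FAProfile(restricted, normalize=True)
    out.zero_filled = missing
    return out


def essential_fa_sum(profile: Mapping[str, float]) -> float:
    """Sum of the major essential FAs 20:5n3 + 22:6n3 + 20:4n6 (mass percent).

    Missing FAs contribute zero.
    """
    return float(sum(profile.get(name, 0.0) for name in ESSENTIAL_FAS))


def extended_dietary_subset() -> tuple[str, ...]:
    """The shipped extended-dietary FA list (39 names).

    FAs deposited in predator tissue largely unmodified from diet.  Shipped as
    an editable data file (``data/extended_dietary_fas.txt``); laboratories
    using a different FA panel should edit or replace it.
    """
    text = resources.files("trophoniche.data").joinpath("extended_dietary_fas.txt").read_text()
    names = tuple(line.strip() for line in text.splitlines() if line.strip() and not line.startswith("#"))
    return names
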