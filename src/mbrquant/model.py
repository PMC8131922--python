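"""Core domain types for label-free quantification with match-between-runs.

Units used throughout the package: m/z in thomson (Th), retention time in
minutes, ion mobility as inverse reduced mobility (1/K0), intensity in
arbitrary units, FAIMS compensation voltage in volts.  All intervals are
closed; m/z tolerances are in ppm.
"""
from __future__ import annotations

import dataclasses
from typing import NamedTuple

import numpy as np

#: Proton mass in Da.
PROTON_MASS = 1.00727646688
#: Averaged spacing between successive peptide isotope peaks, Th at charge 1.
ISOTOPE_SPACING = 1.00286864
#: Coefficient of the Poisson rate lambda = c * mass used for the theoretical
#: peptide isotope envelope (averagine-style approximation).
DEFAULT_LAMBDA_COEF = 4.9384e-4


class ValidationError(ValueError):
    """A domain invariant was violated by input data."""


class IonKey(NamedTuple):
    """The unit of quantification: peptide sequence + modifications + charge.

    Equality is exact on all three fields.  ``modifications`` is the
    canonical serialization produced by :func:`canonical_modifications`.
    """

    sequence: str
    modifications: str
    charge: int


def canonical_modifications(mods: str | None) -> str:
    """Canonicalize a modification string to sorted ``pos:deltamass`` tokens.

    Tokens are comma-separated ``position:delta`` pairs; they are sorted by
    integer position.  ``None``, ``""`` and NaN-like inputs map to ``""``
    (unmodified).
    """
    if mods is None:
        return ""
    text = str(mods).strip()
    if not text or text.lower() == "nan":
        return ""
    tokens = []
    for tok in text.split(","):
        tok = tok.strip()
        if not tok:
            continue
        pos_s, _, delta_s = tok.partition(":")
        try:
            pos = int(pos_s)
            delta = float(delta_s)
        except ValueError as exc:
            raise ValidationError(f"malformed modification token {tok!r}") from exc
        tokens.append((pos, delta))
    tokens.sort(key=lambda t: t[0])
    return ",".join(f"{p}:{d:g}" for p, d in tokens)


def modification_mass(mods: str) -> float:
    """Total delta mass (Da) of a canonical modification string."""
    if not mods:
        return 0.0
    return sum(float(tok.partition(":")[2]) for tok in mods.split(","))


def theoretical_mz(ion: IonKey) -> float:
    """Theoretical m/z of an ion from its sequence, modifications and charge.

    Uses monoisotopic residue masses (via pyteomics).  Raises ``ValueError``
    for sequences containing non-standard residues.
    """
    from pyteomics import mass as _mass

    mz = _mass.fast_mass(ion.sequence, charge=ion.charge)
    return mz + modification_mass(ion.modifications) / ion.charge


@dataclasses.dataclass(frozen=True)
class Peak:
    """One centroided signal."""

    mz: float
    rt: float
    intensity: float
    im: float | None = None
    faims_cv: float | None = None

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValidationError(f"peak m/z must be positive, got {self.mz}")
        if self.rt < 0:
            raise ValidationError(f"peak RT must be non-negative, got {self.rt}")
        if self.intensity < 0:
            raise ValidationError(
                f"peak intensity must be non-negative, got {self.intensity}"
            )
        if self.im is not None and self.im <= 0:
            raise ValidationError(f"peak 1/K0 must be positive, got {self.im}")


@dataclasses.dataclass
class RunPeakMap:
    """All centroided peaks of one LC-MS run, sorted by (faims_cv, mz, rt).

    Columns are parallel numpy arrays.  ``im`` and ``faims_cv`` are either
    present for every peak or absent entirely (``None``).
    """

    run_id: str
    mz: np.ndarray
    rt: np.ndarray
    intensity: np.ndarray
    im: np.ndarray | None = None
    faims_cv: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=np.float64)
        self.rt = np.asarray(self.rt, dtype=np.float64)
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        n = self.mz.size
        for name in ("rt", "intensity"):
            if getattr(self, name).size != n:
                raise ValidationError(f"column {name!r} length mismatch")
        if self.im is not None:
            self.im = np.asarray(self.im, dtype=np.float64)
            if self.im.size != n:
                raise ValidationError("column 'im' length mismatch")
        if self.faims_cv is not None:
            self.faims_cv = np.asarray(self.faims_cv, dtype=np.float64)
            if self.faims_cv.size != n:
                raise ValidationError("column 'faims_cv' length mismatch")
        self._validate()
        self._sort()

    def _validate(self) -> None:
        if self.mz.size == 0:
            return
        bad = np.flatnonzero(self.intensity < 0)
        if bad.size:
            raise ValidationError(
                f"run {self.run_id!r}: negative intensity at row {bad[0]}"
            )
        bad = np.flatnonzero(self.mz <= 0)
        if bad.size:
            raise ValidationError(f"run {self.run_id!r}: non-positive m/z at row {bad[0]}")
        bad = np.flatnonzero(self.rt < 0)
        if bad.size:
            raise ValidationError(f"run {self.run_id!r}: negative RT at row {bad[0]}")
        if self.im is not None:
            if np.isnan(self.im).any():
                raise ValidationError(
                    f"run {self.run_id!r}: mixed ion-mobility presence "
                    "(all peaks must have IM or none)"
                )
            bad = np.flatnonzero(self.im <= 0)
            if bad.size:
                raise ValidationError(
                    f"run {self.run_id!r}: non-positive 1/K0 at row {bad[0]}"
                )
        if self.faims_cv is not None and np.isnan(self.faims_cv).any():
            raise ValidationError(
                f"run {self.run_id!r}: mixed FAIMS CV presence"
            )

    def _sort(self) -> None:
        # np.lexsort: last key is primary -> (cv, mz, rt) total order.
        keys = [self.rt, self.mz]
        if self.faims_cv is not None:
            keys.append(self.faims_cv)
        order = np.lexsort(tuple(keys))
        self.mz = self.mz[order]
        self.rt = self.rt[order]
        self.intensity = self.intensity[order]
        if self.im is not None:
            self.im = self.im[order]
        if self.faims_cv is not None:
            self.faims_cv = self.faims_cv[order]

    def __len__(self) -> int:
        return int(self.mz.size)

    @property
    def cv_values(self) -> tuple[float, ...]:
        """Distinct compensation voltages, sorted; empty when CV absent."""
        if self.faims_cv is None or self.faims_cv.size == 0:
            return ()
        return tuple(np.unique(self.faims_cv))

    @property
    def single_cv(self) -> bool:
        return len(self.cv_values) <= 1

    @classmethod
    def from_peaks(cls, run_id: str, peaks: list[Peak]) -> "RunPeakMap":
        has_im = any(p.im is not None for p in peaks)
        has_cv = any(p.faims_cv is not None for p in peaks)
        if has_im and not all(p.im is not None for p in peaks):
            raise ValidationError("mixed ion-mobility presence in peak list")
        if has_cv and not all(p.faims_cv is not None for p in peaks):
            raise ValidationError("mixed FAIMS CV presence in peak list")
        return cls(
            run_id=run_id,
            mz=np.array([p.mz for p in peaks]),
            rt=np.array([p.rt for p in peaks]),
            intensity=np.array([p.intensity for p in peaks]),
            im=np.array([p.im for p in peaks]) if has_im else None,
            faims_cv=np.array([p.faims_cv for p in peaks]) if has_cv else None,
        )

    def mz_slice(self, lo: float, hi: float) -> tuple[int, int]:
        """Index range [i0, i1) of peaks with mz in the closed window [lo, hi].

        Valid only on single-CV maps (the global sort is then by m/z).
        """
        i0 = int(np.searchsorted(self.mz, lo, side="left"))
        i1 = int(np.searchsorted(self.mz, hi, side="right"))
        return i0, i1


def partition_by_cv(pmap: RunPeakMap) -> dict[float | None, RunPeakMap]:
    """Split a peak map into one map per FAIMS compensation voltage.

    Maps without a CV column yield a single partition keyed by ``None``.
    An empty map yields an empty partition set.  The union of partitions is
    a permutation of the input peaks.
    """
    if len(pmap) == 0:
        return {}
    if pmap.faims_cv is None:
        return {None: pmap}
    out: dict[float | None, RunPeakMap] = {}
    for cv in pmap.cv_values:
        mask = pmap.faims_cv == cv
        out[float(cv)] = RunPeakMap(
            run_id=pmap.run_id,
            mz=pmap.mz[mask],
            rt=pmap.rt[mask],
            intensity=pmap.intensity[mask],
            im=None if pmap.im is None else pmap.im[mask],
            faims_cv=pmap.faims_cv[mask],
        )
    return out


@dataclasses.dataclass
class PsmRecord:
    """One peptide-spectrum match with calibrated precursor coordinates."""

    ion: IonKey
    run_id: str
    calibrated_mz: float
    rt: float
    im: float | None = None
    faims_cv: float | None = None
    protein_ids: tuple[str, ...] = ()
    probability: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValidationError(
                f"PSM probability must be in [0,1], got {self.probability}"
            )
        self.protein_ids = tuple(self.protein_ids)


@dataclasses.dataclass
class TracedFeature:
    """A quantified chromatographic feature.

    ``intensity`` is an area (without ion mobility) or a volume (with ion
    mobility).  ``isotope_intensities`` are the integrated 0/+1/+2 isotope
    areas on a common scheme (no background subtraction) used for envelope
    scoring.  ``mass_error_ppm`` is signed, measured vs. the query m/z.
    """

    mono_mz: float
    charge: int
    rt_apex: float
    rt_start: float
    rt_end: float
    intensity: float
    isotope_intensities: tuple[float, float, float]
    mass_error_ppm: float
    im_center: float | None = None

    def __post_init__(self) -> None:
        if not (self.rt_start <= self.rt_apex <= self.rt_end):
            raise ValidationError("feature requires rt_start <= rt_apex <= rt_end")
        if self.intensity < 0:
            raise ValidationError("feature intensity must be non-negative")
        if any(v < 0 for v in self.isotope_intensities):
            raise ValidationError("isotope intensities must be non-negative")


MSMS = "MSMS"
MBR = "MBR"


@dataclasses.dataclass
class QuantRow:
    """One quantified ion in one run, from direct MS/MS or from transfer."""

    run_id: str
    ion: IonKey
    feature: TracedFeature | None
    source: str  # MSMS | MBR
    protein_ids: tuple[str, ...]
    intensity: float
    transfer_probability: float | None = None

    def __post_init__(self) -> None:
        if self.source not in (MSMS, MBR):
            raise ValidationError(f"unknown source {self.source!r}")
        if self.source == MSMS and self.transfer_probability is not None:
            raise ValidationError("MS/MS rows must not carry a transfer probability")
        if self.intensity < 0:
            raise ValidationError("row intensity must be non-negative")
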