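"""Seeded synthesis of DDA runs containing co-isolated light/heavy nitropeptide pairs.

The generator emulates the acquisition regime the pipeline targets: survey
scans over m/z 400-2000, MS/MS on the top-N most intense precursors with a
wide (default 5 m/z) isolation window and 30-s dynamic exclusion.  Because a
light/heavy nitropeptide pair is spaced by exactly 0.9970349/z, the wide
window guarantees co-isolation: every MS2 scan on either member contains
fragment and reporter ions of both, which is what makes per-scan reporter
ratio quantitation possible.

Each run is emitted together with a manifest recording, per MS2 scan, the
true contributing species and true (pre-noise) reporter intensities — the
ground truth against which detection and quantitation are validated.

Deliberate simplifications: Gaussian elution profiles, flat per-series
fragment intensities, three MS1 isotope sticks per species, and singly
charged fragments only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .chem import (
    ElementalComposition,
    MODIFICATIONS,
    Peptide,
    PROTON_MASS,
    fragment_ions,
    immonium,
)
from .isotopes import fine_structure, reporter_interference_fractions
from .spectra_io import PrecursorInfo, Run, Spectrum

__all__ = [
    "SimulatedSpecies",
    "AcquisitionConfig",
    "NoiseModel",
    "generate_run",
    "table1_fixture",
    "TABLE1_NOMINAL_RATIOS",
]

MS2_RANGE = (100.0, 2000.0)
#: Apex MS1 intensity of a species at unit abundance (arbitrary counts).
MS1_SCALE = 1.0e6
#: Apex intensity of each backbone fragment ion at unit abundance.
FRAGMENT_SCALE = 2.0e4
#: Apex intensity of the nitrotyrosine reporter ion at unit abundance.  The
#: reporter is set well above backbone fragments, reflecting the strong
#: immonium yield of nitrotyrosine under beam-type (HCD) fragmentation.
REPORTER_SCALE = 1.0e5
#: Species contributions below this apex fraction are dropped from a scan.
ELUTION_FLOOR = 1e-4


@dataclass(frozen=True)
class SimulatedSpecies:
    """One analyte: a peptide at a charge state with a Gaussian elution peak."""

    name: str
    peptide: Peptide
    charge: int
    abundance: float
    rt_center: float  # minutes
    rt_sigma: float   # minutes (Gaussian sigma)

    def __post_init__(self) -> None:
        if self.abundance <= 0:
            raise ValueError("abundance must be positive")
        if self.rt_sigma <= 0:
            raise ValueError("elution width must be positive")

    def elution(self, t: float) -> float:
        z = (t - self.rt_center) / self.rt_sigma
        return float(np.exp(-0.5 * z * z))


@dataclass(frozen=True)
class AcquisitionConfig:
    """Data-dependent acquisition settings."""

    mz_range: tuple[float, float] = (400.0, 2000.0)
    top_n: int = 3
    isolation_width: float = 5.0
    dynamic_exclusion_s: float = 30.0
    repeat_count: int = 1
    ms1_resolution: float = 240_000.0
    ms2_resolution: float = 120_000.0
    cycle_time_s: float = 3.0
    run_length_min: float | None = None

    def __post_init__(self) -> None:
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")
        if self.isolation_width <= 0:
            raise ValueError("isolation width must be positive")
        if self.cycle_time_s <= 0:
            raise ValueError("cycle time must be positive")


@dataclass(frozen=True)
class NoiseModel:
    """Stochastic perturbations applied after the clean scan is assembled.

    Background MS2 peaks are drawn uniformly in m/z, excluding a guard band
    of ``reporter_guard_da`` around both reporter masses so that noise-free
    specificity statements stay exact; ``adversarial_decoys`` instead plants
    near-reporter decoys 0.01-0.05 Da away to exercise tolerance logic.
    """

    background_peaks: int = 30
    background_mean_intensity: float = 300.0
    mz_jitter_ppm: float = 1.5
    intensity_sigma: float = 0.08
    reporter_guard_da: float = 0.02
    adversarial_decoys: bool = False

    @classmethod
    def none(cls) -> "NoiseModel":
        return cls(background_peaks=0, mz_jitter_ppm=0.0, intensity_sigma=0.0)


def _nitro_channel(species: SimulatedSpecies) -> str | None:
    for _pos, mod in species.peptide.modifications:
        if mod.name == "nitro_light":
            return "light"
        if mod.name == "nitro_heavy":
            return "heavy"
    return None


def _ms1_sticks(species: SimulatedSpecies) -> list[tuple[float, float]]:
    """Monoisotopic + first two aggregated isotope peaks as (m/z, rel. abundance)."""
    comp = species.peptide.composition()
    pattern = fine_structure(comp, prune_below=1e-5)
    mono = pattern.masses[0]
    clusters: dict[int, tuple[float, float]] = {}
    for m, a in pattern.sticks():
        k = int(round(m - mono))
        wm, wa = clusters.get(k, (0.0, 0.0))
        clusters[k] = (wm + m * a, wa + a)
    sticks = []
    base = clusters[0][1]
    for k in (0, 1, 2):
        if k in clusters:
            wm, wa = clusters[k]
            mass = wm / wa
            sticks.append(((mass + species.charge * PROTON_MASS) / species.charge, wa / base))
    return sticks


def _reporter(species: SimulatedSpecies) -> tuple[str, float] | None:
    channel = _nitro_channel(species)
    if channel is None:
        return None
    mod = MODIFICATIONS["nitro_light" if channel == "light" else "nitro_heavy"]
    return channel, immonium("Y", [mod]).mz


def generate_run(
    species: list[SimulatedSpecies],
    acq: AcquisitionConfig | None = None,
    noise: NoiseModel | None = None,
    seed: int = 0,
    isotope_interference: bool = False,
) -> tuple[Run, pd.DataFrame]:
    """Simulate one DDA run and its ground-truth manifest.

    With ``isotope_interference`` the light reporter's single-15N satellite is
    added on top of the heavy reporter position (and its 13C satellite 0.0063
    Da above it); by default reporter sticks carry only their nominal species
    intensity, so noise-free ratios equal the abundance ratios exactly.
    """
    if not species:
        raise ValueError("at least one species is required")
    acq = acq or AcquisitionConfig()
    noise = noise or NoiseModel()
    rng = np.random.default_rng(seed)

    run_length = acq.run_length_min
    if run_length is None:
        run_length = max(s.rt_center + 4 * s.rt_sigma for s in species) + 0.25
    for s in species:
        if s.rt_center < 0 or s.rt_center > run_length:
            raise ValueError(
                f"species {s.name} elutes at {s.rt_center} min, outside run of "
                f"{run_length} min"
            )

    f15n, f13c, d1315 = reporter_interference_fractions()
    pre = []
    for s in species:
        pre.append(
            {
                "species": s,
                "sticks": _ms1_sticks(s),
                "mono_mz": s.peptide.mz(s.charge),
                "fragments": [
                    (ion.mz, FRAGMENT_SCALE)
                    for ion in fragment_ions(s.peptide, ("b", "y"), 1)
                    if MS2_RANGE[0] <= ion.mz <= MS2_RANGE[1]
                ],
                "reporter": _reporter(s),
            }
        )

    cycle_min = acq.cycle_time_s / 60.0
    spectra: list[Spectrum] = []
    manifest_rows: list[dict] = []
    scan_no = 0
    selection_log: dict[float, list[float]] = {}

    def jitter_and_pack(
        peaks: dict[float, float], lo: float, hi: float, reporters: tuple[float, ...]
    ) -> tuple[np.ndarray, np.ndarray]:
        mzs, intens = [], []
        for m, i in peaks.items():
            if i <= 0:
                continue
            if noise.mz_jitter_ppm > 0:
                m = m * (1.0 + rng.normal(0.0, noise.mz_jitter_ppm) * 1e-6)
            if noise.intensity_sigma > 0:
                i = i * float(np.exp(rng.normal(0.0, noise.intensity_sigma)))
            mzs.append(m)
            intens.append(i)
        for _ in range(noise.background_peaks):
            while True:
                m = float(rng.uniform(lo, hi))
                if all(abs(m - r) > noise.reporter_guard_da for r in reporters):
                    break
            mzs.append(m)
            intens.append(float(rng.exponential(noise.background_mean_intensity)))
        if noise.adversarial_decoys:
            for r in reporters:
                off = float(rng.uniform(0.01, 0.05)) * (1 if rng.random() < 0.5 else -1)
                mzs.append(r + off)
                intens.append(float(rng.exponential(noise.background_mean_intensity) * 5))
        if not mzs:
            return np.array([]), np.array([])
        mz_arr = np.asarray(mzs)
        i_arr = np.asarray(intens)
        order = np.argsort(mz_arr)
        mz_arr, i_arr = mz_arr[order], i_arr[order]
        uniq, inverse = np.unique(mz_arr, return_inverse=True)
        summed = np.zeros_like(uniq)
        np.add.at(summed, inverse, i_arr)
        return uniq, summed

    reporter_mzs = tuple(
        sorted({p["reporter"][1] for p in pre if p["reporter"] is not None})
    )

    t = 0.0
    while t < run_length:
        # ---- survey scan -------------------------------------------------
        ms1_peaks: dict[float, float] = {}
        candidates: list[tuple[float, float, dict]] = []
        for p in pre:
            s = p["species"]
            el = s.elution(t)
            if el < ELUTION_FLOOR:
                continue
            apex = s.abundance * MS1_SCALE * el
            for mzv, rel in p["sticks"]:
                if acq.mz_range[0] <= mzv <= acq.mz_range[1]:
                    ms1_peaks[mzv] = ms1_peaks.get(mzv, 0.0) + apex * rel
            if acq.mz_range[0] <= p["mono_mz"] <= acq.mz_range[1]:
                candidates.append((apex, p["mono_mz"], p))
        scan_no += 1
        mz_arr, i_arr = jitter_and_pack(ms1_peaks, *acq.mz_range, reporters=())
        spectra.append(
            Spectrum(
                id=f"scan={scan_no}",
                ms_level=1,
                rt_min=round(t, 6),
                mz=mz_arr,
                intensity=i_arr,
                resolution=acq.ms1_resolution,
            )
        )

        # ---- top-N selection with dynamic exclusion ----------------------
        candidates.sort(key=lambda c: -c[0])
        selected = []
        for apex, mono_mz, p in candidates:
            if len(selected) >= acq.top_n:
                break
            key = round(mono_mz, 4)
            recent = [
                ts for ts in selection_log.get(key, [])
                if (t - ts) * 60.0 <= acq.dynamic_exclusion_s
            ]
            if len(recent) > acq.repeat_count:
                continue
            selection_log.setdefault(key, []).append(t)
            selected.append((mono_mz, p))

        # ---- MS2 scans ---------------------------------------------------
        for frac, (center, picked) in enumerate(selected):
            ms2_time = t + (frac + 1) * cycle_min / (acq.top_n + 1)
            contributing = [
                p for p in pre
                if abs(p["mono_mz"] - center) <= acq.isolation_width / 2.0
                and p["species"].abundance * p["species"].elution(ms2_time) > 0.0
            ]
            peaks: dict[float, float] = {}
            true_light = 0.0
            true_heavy = 0.0
            names = []
            for p in contributing:
                s = p["species"]
                scale = s.abundance * s.elution(ms2_time)
                names.append(s.name)
                for fm, fi in p["fragments"]:
                    peaks[fm] = peaks.get(fm, 0.0) + fi * scale
                rep = p["reporter"]
                if rep is not None:
                    channel, rep_mz = rep
                    inten = REPORTER_SCALE * scale
                    peaks[rep_mz] = peaks.get(rep_mz, 0.0) + inten
                    if channel == "light":
                        true_light += inten
                        if isotope_interference:
                            heavy_mz = rep_mz + (
                                immonium("Y", [MODIFICATIONS["nitro_heavy"]]).mz
                                - immonium("Y", [MODIFICATIONS["nitro_light"]]).mz
                            )
                            peaks[heavy_mz] = peaks.get(heavy_mz, 0.0) + f15n * inten
                            c13_mz = heavy_mz + d1315
                            peaks[c13_mz] = peaks.get(c13_mz, 0.0) + f13c * inten
                    else:
                        true_heavy += inten
            scan_no += 1
            sid = f"scan={scan_no}"
            mz_arr, i_arr = jitter_and_pack(peaks, *MS2_RANGE, reporters=reporter_mzs)
            top = picked["species"]
            spectra.append(
                Spectrum(
                    id=sid,
                    ms_level=2,
                    rt_min=round(ms2_time, 6),
                    mz=mz_arr,
                    intensity=i_arr,
                    precursor=PrecursorInfo(
                        selected_mz=center,
                        charge=top.charge,
                        isolation_center=center,
                        isolation_width=acq.isolation_width,
                    ),
                    resolution=acq.ms2_resolution,
                )
            )
            manifest_rows.append(
                {
                    "scan_id": sid,
                    "rt_min": round(ms2_time, 6),
                    "precursor_mz": center,
                    "species": ";".join(names),
                    "true_light": true_light,
                    "true_heavy": true_heavy,
                    "true_ratio": (true_light / true_heavy) if true_heavy > 0 else np.nan,
                }
            )
        t += cycle_min

    manifest = pd.DataFrame(
        manifest_rows,
        columns=[
            "scan_id", "rt_min", "precursor_mz", "species",
            "true_light", "true_heavy", "true_ratio",
        ],
    )
    run = Run(spectra=spectra, metadata="nitroquant synthetic DDA run")
    return run, manifest


# ---------------------------------------------------------------------------
# The mixing-design fixture
# ---------------------------------------------------------------------------

#: Nominal light:heavy mixing ratios of the five fixture runs.
TABLE1_NOMINAL_RATIOS: dict[str, float] = {
    "reference": 1.0,
    "0.25a": 0.25,
    "0.25b": 0.25,
    "0.25c": 0.25,
    "0.10": 0.10,
}

_BSA_NITROPEPTIDES = [
    ("YLYEIAR", "1:{ch}", 2, 2.0),
    ("YICDNQDTISSK", "1:{ch} 3:cam", 2, 4.0),
]

_BACKGROUND_PEPTIDES = [
    ("LVNELTEFAK", 2, 1.2, 1.0),
    ("HLVDEPQNLIK", 2, 0.8, 3.0),
    ("AEFVEVTK", 2, 1.5, 5.0),
]


def _fixture_species(light_to_heavy: float) -> list[SimulatedSpecies]:
    species: list[SimulatedSpecies] = []
    for seq, modfmt, charge, rt in _BSA_NITROPEPTIDES:
        for channel, abundance in (
            ("nitro_light", light_to_heavy),
            ("nitro_heavy", 1.0),
        ):
            pep = Peptide.parse(f"{seq} {modfmt.format(ch=channel)}")
            species.append(
                SimulatedSpecies(
                    name=f"{seq}[{channel}]",
                    peptide=pep,
                    charge=charge,
                    abundance=abundance,
                    rt_center=rt,
                    rt_sigma=0.15,
                )
            )
    for seq, charge, abundance, rt in _BACKGROUND_PEPTIDES:
        species.append(
            SimulatedSpecies(
                name=seq,
                peptide=Peptide.parse(seq),
                charge=charge,
                abundance=abundance,
                rt_center=rt,
                rt_sigma=0.2,
            )
        )
    return species


def table1_fixture(
    seed: int,
    noise: NoiseModel | None = None,
    background: bool = True,
) -> dict[str, tuple[Run, pd.DataFrame, float]]:
    """Five runs emulating the spike-in mixing design.

    One 1:1 reference, three 0.25:1 light:heavy replicates with distinct
    seeds, and one 0.10:1 run.  Each run contains the two BSA nitropeptides
    Y*LYEIAR and Y*IC(cam)DNQDTISSK as co-eluting light/heavy pairs, plus
    unmodified background peptides competing for MS/MS selection.

    Returns ``{name: (run, manifest, nominal_light_to_heavy)}``.
    """
    out: dict[str, tuple[Run, pd.DataFrame, float]] = {}
    for k, (name, ratio) in enumerate(TABLE1_NOMINAL_RATIOS.items()):
        species = _fixture_species(ratio)
        if not background:
            species = [s for s in species if "[" in s.name]
        run, manifest = generate_run(
            species,
            acq=AcquisitionConfig(run_length_min=6.0),
            noise=noise,
            seed=(seed * 10 + k) % (2**31),
        )
        out[name] = (run, manifest, ratio)
    return out
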