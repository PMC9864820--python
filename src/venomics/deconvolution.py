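"""Charge-state deconvolution of intact-protein ESI spectra.

The stage mirrors how abundant venom toxins are extracted from an LC-MS run:

1. locate elution windows as peaks of the total ion chromatogram,
2. average the centroid spectra inside each window,
3. assign charge states: every (peak, z) pair proposes a neutral mass
   ``z·(mz − m_p)``; proposals that agree within a flat Da tolerance form a
   charge envelope, and envelopes are accepted greedily by support
   (distinct charges, then summed intensity, ties to the lower mass),
4. refine each envelope with an extracted ion chromatogram (EIC) at its
   highest-intensity charge state, giving the retention-time apex and the
   abundance used to rank toxins.

No isotope information is used: inputs are single centroids per charge
state, and masses are reported as single neutral masses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .errors import ValidationError
from .simulate import PROTON_MASS
from .spectra_io import Chromatogram, Run, total_ion_chromatogram

__all__ = [
    "Peak",
    "ChargeEnvelope",
    "DeconvolvedToxin",
    "ElutionWindow",
    "DeconvParams",
    "detect_elution_windows",
    "average_spectrum",
    "deconvolve",
    "extract_eic",
    "top_abundant_toxins",
]


@dataclass(frozen=True)
class Peak:
    """A single centroid in an averaged spectrum."""

    mz: float
    intensity: float

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValidationError("peak m/z must be positive")
        if self.intensity < 0:
            raise ValidationError("peak intensity must be non-negative")


@dataclass
class ChargeEnvelope:
    """A neutral mass supported by one or more charge states.

    ``members`` holds ``(z, observed m/z, intensity)`` triples with distinct
    charges; ``score`` is the (distinct-charge count, summed intensity)
    support metric used during greedy selection.
    """

    neutral_mass: float
    members: list[tuple[int, float, float]]
    score: tuple[int, float]

    @property
    def charges(self) -> tuple[int, ...]:
        return tuple(m[0] for m in self.members)

    @property
    def best_member(self) -> tuple[int, float, float]:
        """Highest-intensity member (ties to the lower charge)."""
        return max(self.members, key=lambda m: (m[2], -m[0]))


@dataclass
class DeconvolvedToxin:
    """An abundant toxin of one run: neutral mass, elution apex, abundance."""

    sample_id: str
    neutral_mass: float
    rt_apex: float
    best_charge: int
    charge_states: tuple[int, ...]
    apex_intensity: float

    def __post_init__(self) -> None:
        if self.neutral_mass <= 0:
            raise ValidationError("neutral_mass must be positive")
        if self.best_charge not in self.charge_states:
            raise ValidationError("best_charge must be one of charge_states")
        if self.apex_intensity < 0:
            raise ValidationError("apex_intensity must be non-negative")


@dataclass(frozen=True)
class ElutionWindow:
    rt_start: float
    rt_end: float
    apex_rt: float

    def __post_init__(self) -> None:
        if not self.rt_start < self.rt_end:
            raise ValidationError("rt_start must be < rt_end")
        if not self.rt_start <= self.apex_rt <= self.rt_end:
            raise ValidationError("apex_rt must lie inside the window")


@dataclass
class DeconvParams:
    """Tunable parameters of the abundant-toxin extraction stage.

    ``min_snr`` gates TIC apexes against the median TIC; ``mz_merge_tol`` is
    the single-linkage m/z tolerance of spectrum averaging;
    ``mass_cluster_tol`` is the flat neutral-mass tolerance at which charge
    proposals agree; masses above ``small_mass_cutoff`` need at least
    ``min_charges`` distinct charge states (small peptides often show one).
    ``min_peak_intensity_rel`` discards averaged peaks below this fraction
    of the window's base peak before deconvolution — chemical-noise
    centroids average down to tiny intensities and would otherwise flood
    the candidate list. ``min_eic_points`` requires an extracted toxin's
    EIC apex to be chromatographic: at least this many consecutive scans at
    or above half the apex (an eluting protein spans many scans, a chemical-
    noise spike exactly one).
    """

    min_snr: float = 1.5
    mz_merge_tol: float = 0.02
    z_min: int = 1
    z_max: int = 30
    mass_cluster_tol: float = 0.1
    min_charges: int = 2
    small_mass_cutoff: float = 5000.0
    eic_mz_tol: float = 0.05
    dedup_mass_tol: float = 1.0
    dedup_rt_tol: float = 0.5
    max_envelopes_per_window: int = 15
    min_peak_intensity_rel: float = 1e-3
    min_eic_points: int = 3
    cover_gaps: bool = True


# ---------------------------------------------------------------------------
# elution windows


def detect_elution_windows(tic: Chromatogram, min_snr: float = 3.0) -> list[ElutionWindow]:
    """Find disjoint elution windows around significant TIC maxima.

    An apex must be a local maximum with value ≥ ``min_snr × median(TIC)``.
    Each window extends from its apex to the nearest points where the TIC
    drops below half the apex, truncated where a neighbouring window begins
    (the boundary is drawn at the TIC minimum between adjacent apexes).
    """
    if len(tic) == 0:
        raise ValidationError("empty chromatogram")
    inten = tic.intensity
    if not np.any(inten > 0):
        return []
    threshold = max(min_snr * float(np.median(inten)), np.finfo(float).tiny)
    apexes, _ = find_peaks(inten, height=threshold)
    if apexes.size == 0:
        return []

    # draw boundaries between adjacent apexes at the interior TIC minimum
    boundaries = [0]
    for a, b in zip(apexes[:-1], apexes[1:]):
        boundaries.append(a + int(np.argmin(inten[a : b + 1])))
    boundaries.append(len(inten) - 1)

    windows: list[ElutionWindow] = []
    for k, apex in enumerate(apexes):
        half = inten[apex] / 2.0
        left = apex
        while left > boundaries[k] and inten[left - 1] >= half:
            left -= 1
        right = apex
        while right < boundaries[k + 1] and inten[right + 1] >= half:
            right += 1
        if left == right:  # degenerate single-point window: pad one scan
            left = max(left - 1, 0)
            right = min(right + 1, len(inten) - 1)
        if left == right:
            continue
        windows.append(ElutionWindow(float(tic.rt[left]), float(tic.rt[right]), float(tic.rt[apex])))
    return windows


# ---------------------------------------------------------------------------
# spectrum averaging


def average_spectrum(run: Run, window: ElutionWindow, mz_merge_tol: float = 0.05) -> list[Peak]:
    """Average the spectra inside an elution window into one peak list.

    Centroids pooled over all in-window spectra are merged by single-linkage
    in m/z (split at gaps larger than ``mz_merge_tol``); each merged peak's
    m/z is the intensity-weighted mean of its centroids and its intensity is
    the mean over the in-window spectra (scans lacking the peak count as
    zero). The result is sorted by m/z.
    """
    in_window = [s for s in run.spectra if window.rt_start <= s.rt <= window.rt_end]
    if not in_window:
        return []
    mz = np.concatenate([s.mz for s in in_window]) if in_window else np.empty(0)
    inten = np.concatenate([s.intensity for s in in_window])
    if mz.size == 0:
        return []
    order = np.argsort(mz, kind="stable")
    mz, inten = mz[order], inten[order]
    split = np.flatnonzero(np.diff(mz) > mz_merge_tol) + 1
    n_spec = len(in_window)
    peaks: list[Peak] = []
    for seg_mz, seg_int in zip(np.split(mz, split), np.split(inten, split)):
        total = seg_int.sum()
        center = float(np.average(seg_mz, weights=seg_int)) if total > 0 else float(seg_mz.mean())
        peaks.append(Peak(mz=center, intensity=float(total / n_spec)))
    return peaks


# ---------------------------------------------------------------------------
# charge-state assignment


def _window_members(
    masses: np.ndarray,
    charges: np.ndarray,
    peak_idx: np.ndarray,
    intensities: np.ndarray,
    start: int,
    stop: int,
) -> dict[int, tuple[int, float, float]]:
    """Per-charge best candidate inside candidates[start:stop] (sorted by mass).

    Each source peak contributes at most once: if one peak appears at two
    charges inside the window, only its higher-intensity proposal is kept.
    """
    best_by_charge: dict[int, tuple[int, float, float]] = {}  # z -> (peak, inten, mass)
    used_peaks: dict[int, int] = {}  # peak -> z currently using it
    for i in range(start, stop):
        z = int(charges[i])
        p = int(peak_idx[i])
        inten = float(intensities[i])
        if p in used_peaks and used_peaks[p] != z:
            continue  # peak already supports another charge in this window
        cur = best_by_charge.get(z)
        if cur is None or inten > cur[1] or (inten == cur[1] and masses[i] < cur[2]):
            if cur is not None:
                used_peaks.pop(cur[0], None)
            best_by_charge[z] = (p, inten, float(masses[i]))
            used_peaks[p] = z
    return best_by_charge


def deconvolve(
    peaks: list[Peak],
    z_min: int = 1,
    z_max: int = 30,
    mass_cluster_tol: float = 0.1,
    min_charges: int = 2,
    small_mass_cutoff: float = 5000.0,
    max_envelopes: int | None = None,
    absorb_tol: float = 1.0,
) -> list[ChargeEnvelope]:
    """Greedy charge-envelope extraction from an averaged peak list.

    Every (peak, z) pair for z in ``[z_min, z_max]`` proposes the neutral
    mass ``z·(mz − m_p)``. Proposals whose masses agree within
    ``mass_cluster_tol`` (a flat Da window over the sorted proposal masses)
    form candidate envelopes scored by (number of distinct supporting
    charges, summed intensity); the best-scoring valid envelope is emitted,
    its peaks are consumed, and the search repeats. Envelopes above
    ``small_mass_cutoff`` require ≥ ``min_charges`` distinct charges; below
    it a single charge suffices. Ties are broken toward the lower neutral
    mass, which also resolves harmonic ambiguity (a true envelope at mass M
    scores identically at 2M with doubled charges; the lower mass wins).

    After an envelope at mass M is emitted, every remaining peak with a
    candidate mass within ``absorb_tol`` of M is consumed as well (ownership
    sweep). m/z jitter can push one charge state's implied mass just outside
    ``mass_cluster_tol``; without the sweep such an orphaned centroid would
    re-emerge as a spurious low-mass single-charge envelope. ``absorb_tol``
    defaults to the 1 Da cross-sample identity tolerance: masses that close
    are the same toxin by definition downstream.
    """
    if not 1 <= z_min <= z_max:
        raise ValidationError("need 1 <= z_min <= z_max")
    if not peaks:
        return []
    peaks = sorted(peaks, key=lambda p: p.mz)

    n_z = z_max - z_min + 1
    p_mz = np.array([p.mz for p in peaks])
    p_int = np.array([p.intensity for p in peaks])
    zs = np.arange(z_min, z_max + 1)
    cand_mass = (zs[None, :] * (p_mz[:, None] - PROTON_MASS)).ravel()
    cand_z = np.broadcast_to(zs[None, :], (len(peaks), n_z)).ravel()
    cand_peak = np.repeat(np.arange(len(peaks)), n_z)
    valid = cand_mass > 0
    order = np.argsort(cand_mass[valid], kind="stable")
    masses = cand_mass[valid][order]
    charges = cand_z[valid][order]
    peak_idx = cand_peak[valid][order]
    intensities = p_int[peak_idx]

    consumed = np.zeros(len(peaks), dtype=bool)
    envelopes: list[ChargeEnvelope] = []
    limit = max_envelopes if max_envelopes is not None else len(peaks)

    while len(envelopes) < limit:
        alive = ~consumed[peak_idx]
        if not np.any(alive):
            break
        a_mass = masses[alive]
        a_z = charges[alive]
        a_peak = peak_idx[alive]
        a_int = intensities[alive]
        n = a_mass.size
        ends = np.searchsorted(a_mass, a_mass + mass_cluster_tol, side="right")
        sizes = ends - np.arange(n)

        best_key = None
        best_window = None

        # singleton windows vectorized: score (1, intensity, mass); valid
        # only below the cutoff unless min_charges allows single support
        single = sizes == 1
        if min_charges > 1:
            single &= a_mass <= small_mass_cutoff
        if np.any(single):
            s_idx = np.flatnonzero(single)
            order = np.lexsort((a_mass[s_idx], -a_int[s_idx]))
            i = int(s_idx[order[0]])
            best_key = (-1, -float(a_int[i]), float(a_mass[i]))
            best_window = (
                {int(a_z[i]): (int(a_peak[i]), float(a_int[i]), float(a_mass[i]))},
                float(a_mass[i]),
                1,
                float(a_int[i]),
            )

        for i in np.flatnonzero(sizes >= 2):
            stop = int(ends[i])
            if i > 0 and stop == int(ends[i - 1]):
                continue  # strict subset of the previous window: cannot score higher
            members = _window_members(a_mass, a_z, a_peak, a_int, int(i), stop)
            n_charges = len(members)
            # fsum: exactly rounded, so equal member sets tie exactly no
            # matter in which order the window enumerated them
            total = math.fsum(m[1] for m in members.values())
            mass_num = math.fsum(m[1] * m[2] for m in members.values())
            est_mass = mass_num / total if total > 0 else float(
                np.mean([m[2] for m in members.values()])
            )
            if est_mass > small_mass_cutoff and n_charges < min_charges:
                continue
            key = (-n_charges, -total, est_mass)
            if best_key is None or key < best_key:
                best_key = key
                best_window = (members, est_mass, n_charges, total)
        if best_window is None:
            break
        members, est_mass, n_charges, total = best_window
        env_members = sorted(
            (z, float(p_mz[p]), inten) for z, (p, inten, _m) in members.items()
        )
        envelopes.append(
            ChargeEnvelope(
                neutral_mass=float(est_mass),
                members=env_members,
                score=(n_charges, float(total)),
            )
        )
        for _z, (p, _i, _m) in members.items():
            consumed[p] = True
        if absorb_tol > 0:
            near = np.abs(masses - est_mass) <= absorb_tol
            consumed[np.unique(peak_idx[near])] = True
    return envelopes


# ---------------------------------------------------------------------------
# EIC extraction and the top-N pipeline


def _eic_index(run: Run):
    """Flattened (sorted m/z, intensity, spectrum index) view of a run.

    Cached on the run instance; keyed by the spectrum count so a structurally
    different run object never reuses a stale index.
    """
    cache = getattr(run, "_eic_cache", None)
    if cache is not None and cache[0] == len(run):
        return cache
    if len(run) and any(len(s) for s in run.spectra):
        flat_mz = np.concatenate([s.mz for s in run.spectra])
        flat_int = np.concatenate([s.intensity for s in run.spectra])
        flat_spec = np.concatenate(
            [np.full(len(s), i, dtype=np.intp) for i, s in enumerate(run.spectra)]
        )
        order = np.argsort(flat_mz, kind="stable")
        cache = (len(run), flat_mz[order], flat_int[order], flat_spec[order])
    else:
        cache = (len(run), np.empty(0), np.empty(0), np.empty(0, dtype=np.intp))
    run._eic_cache = cache
    return cache


def extract_eic(run: Run, mz_center: float, mz_tol: float = 0.05) -> Chromatogram:
    """Per-spectrum summed intensity inside ``mz_center ± mz_tol``."""
    if mz_tol <= 0:
        raise ValidationError("mz_tol must be positive")
    _n, flat_mz, flat_int, flat_spec = _eic_index(run)
    values = np.zeros(len(run))
    a = np.searchsorted(flat_mz, mz_center - mz_tol, side="left")
    b = np.searchsorted(flat_mz, mz_center + mz_tol, side="right")
    if b > a:
        np.add.at(values, flat_spec[a:b], flat_int[a:b])
    return Chromatogram(run.rt, values)


def top_abundant_toxins(
    run: Run,
    n_top: int = 12,
    params: DeconvParams | None = None,
) -> list[DeconvolvedToxin]:
    """Extract the ``n_top`` most abundant deconvolved toxins of a run.

    Envelopes are collected per elution window, refined with an EIC at the
    highest-intensity charge state (apex restricted to the window), pooled,
    deduplicated under the cross-sample identity rule (masses within
    ``dedup_mass_tol`` and apexes within ``dedup_rt_tol`` are the same
    toxin; the more intense record is kept) and ranked by EIC apex
    intensity. Fewer than ``n_top`` found means all found are returned.
    """
    if n_top < 1:
        raise ValidationError("n_top must be >= 1")
    if params is None:
        params = DeconvParams()
    tic = total_ion_chromatogram(run)
    if len(tic) == 0:
        return []
    windows = detect_elution_windows(tic, params.min_snr)
    if params.cover_gaps:
        # Densely co-eluting venoms leave real toxins in TIC valleys that
        # belong to no detected window; average the complementary segments
        # too so the whole run is covered (whole-run fallback, piecewise).
        covered = np.zeros(len(tic), dtype=bool)
        for w in windows:
            covered |= (tic.rt >= w.rt_start) & (tic.rt <= w.rt_end)
        gaps = np.flatnonzero(~covered)
        if gaps.size:
            splits = np.flatnonzero(np.diff(gaps) > 1) + 1
            for seg in np.split(gaps, splits):
                if seg.size < 2 or tic.intensity[seg].max() <= 0:
                    continue
                apex = int(seg[np.argmax(tic.intensity[seg])])
                windows.append(
                    ElutionWindow(
                        float(tic.rt[seg[0]]), float(tic.rt[seg[-1]]), float(tic.rt[apex])
                    )
                )
        windows.sort(key=lambda w: w.rt_start)

    candidates: list[DeconvolvedToxin] = []
    for window in windows:
        peaks = average_spectrum(run, window, params.mz_merge_tol)
        if not peaks:
            continue
        floor = params.min_peak_intensity_rel * max(p.intensity for p in peaks)
        peaks = [p for p in peaks if p.intensity >= floor]
        envelopes = deconvolve(
            peaks,
            z_min=params.z_min,
            z_max=params.z_max,
            mass_cluster_tol=params.mass_cluster_tol,
            min_charges=params.min_charges,
            small_mass_cutoff=params.small_mass_cutoff,
            max_envelopes=params.max_envelopes_per_window,
        )
        in_win = (run.rt >= window.rt_start) & (run.rt <= window.rt_end)
        for env in envelopes:
            z_best, mz_best, _ = env.best_member
            eic = extract_eic(run, mz_best, params.eic_mz_tol)
            masked = np.where(in_win, eic.intensity, -np.inf)
            apex_idx = int(np.argmax(masked))
            # hill-climb to the local EIC maximum over the whole run: an
            # envelope picked up from a peak's tail in an adjacent window
            # must still report the true elution apex, or it would survive
            # deduplication as a shifted duplicate
            while apex_idx > 0 and eic.intensity[apex_idx - 1] > eic.intensity[apex_idx]:
                apex_idx -= 1
            while (
                apex_idx < len(eic) - 1
                and eic.intensity[apex_idx + 1] > eic.intensity[apex_idx]
            ):
                apex_idx += 1
            apex = float(eic.intensity[apex_idx])
            if apex <= 0:
                continue
            # chromatographic plausibility: consecutive scans >= half apex
            half = apex / 2.0
            n_points = 1
            j = apex_idx - 1
            while j >= 0 and eic.intensity[j] >= half:
                n_points += 1
                j -= 1
            j = apex_idx + 1
            while j < len(eic) and eic.intensity[j] >= half:
                n_points += 1
                j += 1
            if n_points < params.min_eic_points:
                continue
            candidates.append(
                DeconvolvedToxin(
                    sample_id=run.metadata.sample_id,
                    neutral_mass=env.neutral_mass,
                    rt_apex=float(eic.rt[apex_idx]),
                    best_charge=int(z_best),
                    charge_states=env.charges,
                    apex_intensity=apex,
                )
            )

    # deterministic ranking (ties prefer the better-supported envelope),
    # then within-run deduplication under the cross-sample identity rule
    candidates.sort(
        key=lambda t: (-t.apex_intensity, -len(t.charge_states), t.neutral_mass, t.rt_apex)
    )
    mz_match = 2.0 * params.eic_mz_tol

    def channel_mzs(t: DeconvolvedToxin) -> list[float]:
        return [(t.neutral_mass + z * PROTON_MASS) / z for z in t.charge_states]

    def best_mz(t: DeconvolvedToxin) -> float:
        return (t.neutral_mass + t.best_charge * PROTON_MASS) / t.best_charge

    kept: list[DeconvolvedToxin] = []
    for cand in candidates:
        duplicate = any(
            abs(cand.neutral_mass - k.neutral_mass) <= params.dedup_mass_tol
            and abs(cand.rt_apex - k.rt_apex) <= params.dedup_rt_tol
            for k in kept
        )
        if duplicate:
            continue
        # One EIC channel at one retention time identifies one toxin. An
        # orphaned charge state of a large toxin can re-emerge as a bogus
        # low-mass single-charge record riding the same trace; whichever
        # interpretation carries more charge-state support wins.
        shadowed = False
        for k in list(kept):
            if abs(cand.rt_apex - k.rt_apex) > params.dedup_rt_tol:
                continue
            if len(cand.charge_states) <= len(k.charge_states):
                if any(abs(best_mz(cand) - mz) <= mz_match for mz in channel_mzs(k)):
                    shadowed = True
                    break
            elif any(abs(best_mz(k) - mz) <= mz_match for mz in channel_mzs(cand)):
                kept.remove(k)
        if not shadowed:
            kept.append(cand)
    return kept[:n_top]
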