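"""Database pooling, the 1-Da + RT identity rule, and presence screening."""

import itertools

import numpy as np
import pytest

from venomics import (
    DeconvolvedToxin,
    PlantedToxin,
    SimulationConfig,
    ValidationError,
    build_database,
    merge_features,
    screen_run,
    synthesize_run,
)
from venomics.screening import ToxinEntry
from venomics.simulate import charge_states_for_mass

from conftest import make_truth


def entry(mass, rt, intensity=100.0, eid=None, sample="S1"):
    return ToxinEntry(
        entry_id=eid or f"{sample}:{mass:.1f}",
        neutral_mass=mass,
        rt_apex=rt,
        charge_states=(4, 5, 6),
        source_sample=sample,
        apex_intensity=intensity,
        best_charge=5,
    )


def toxin_record(sample, mass, rt, intensity=100.0):
    return DeconvolvedToxin(
        sample_id=sample,
        neutral_mass=mass,
        rt_apex=rt,
        best_charge=5,
        charge_states=(4, 5, 6),
        apex_intensity=intensity,
    )


class TestBuildDatabase:
    def test_count_conservation(self):
        toxins = {
            s: [toxin_record(s, 6000.0 + i, 5.0) for i in range(12)] for s in ("A", "B", "C")
        }
        assert len(build_database(toxins)) == 36

    def test_empty_input(self):
        assert build_database({}) == []

    def test_fields_preserved(self):
        rec = toxin_record("A", 6783.0, 12.3, 55.0)
        (e,) = build_database({"A": [rec]})
        assert (e.neutral_mass, e.rt_apex, e.charge_states) == (6783.0, 12.3, (4, 5, 6))
        assert e.source_sample == "A"

    def test_duplicate_sample_ids_rejected(self):
        with pytest.raises(ValidationError):
            build_database([[toxin_record("A", 6000.0, 5.0)], [toxin_record("A", 6001.0, 5.0)]])


class TestIdentityRule:
    def test_masses_within_one_dalton_merge(self):
        features = merge_features([entry(6783.0, 12.30), entry(6783.8, 12.35)], 1.0, 0.5)
        assert len(features) == 1

    def test_masses_beyond_one_dalton_stay_apart(self):
        features = merge_features([entry(6783.0, 12.30), entry(6784.2, 12.30)], 1.0, 0.5)
        assert len(features) == 2

    def test_chain_splits_at_clique_boundary(self):
        # closest pair (0.6 Da) merges first; the clique condition
        # (6784.4 − 6783.0 = 1.4 > 1) blocks further merging
        features = merge_features(
            [entry(6783.0, 12.3), entry(6783.8, 12.3), entry(6784.4, 12.3)], 1.0, 0.5
        )
        groups = sorted(
            sorted(e.neutral_mass for e in f.member_entries) for f in features
        )
        assert groups == [[6783.0], [6783.8, 6784.4]]

    def test_same_mass_different_rt_stays_apart(self):
        features = merge_features([entry(6783.0, 5.0), entry(6783.0, 9.0)], 1.0, 0.5)
        assert len(features) == 2

    def test_clique_property_on_random_entries(self, rng):
        for _ in range(25):
            entries = [
                entry(float(rng.uniform(6780, 6790)), float(rng.uniform(10, 12)), eid=str(i))
                for i in range(int(rng.integers(2, 15)))
            ]
            for f in merge_features(entries, 1.0, 0.5):
                f.check_clique(1.0, 0.5)

    def test_consensus_is_intensity_weighted(self):
        features = merge_features(
            [entry(6783.0, 12.0, intensity=10.0), entry(6783.6, 12.2, intensity=30.0)], 1.0, 0.5
        )
        (f,) = features
        assert f.consensus_mass == pytest.approx((10 * 6783.0 + 30 * 6783.6) / 40)
        assert f.consensus_rt == pytest.approx((10 * 12.0 + 30 * 12.2) / 40)


def exhaustive_maximal_merge(entries, mass_tol, rt_tol):
    """Oracle: all partitions of each connected component; fewest valid blocks.

    Entries farther apart than the tolerances can never share a feature, so
    the exhaustive search factorizes over single-linkage components.
    """

    def ok(block):
        for a, b in itertools.combinations(block, 2):
            if abs(a.neutral_mass - b.neutral_mass) > mass_tol or abs(a.rt_apex - b.rt_apex) > rt_tol:
                return False
        return True

    def partitions(items):
        if not items:
            yield []
            return
        first, rest = items[0], items[1:]
        for part in partitions(rest):
            for i in range(len(part)):
                yield part[:i] + [[first] + part[i]] + part[i + 1 :]
            yield [[first]] + part

    # single-linkage components
    comps = []
    pool = list(entries)
    while pool:
        comp = [pool.pop()]
        changed = True
        while changed:
            changed = False
            for e in pool[:]:
                if any(
                    abs(e.neutral_mass - c.neutral_mass) <= mass_tol
                    and abs(e.rt_apex - c.rt_apex) <= rt_tol
                    for c in comp
                ):
                    pool.remove(e)
                    comp.append(e)
                    changed = True
        comps.append(comp)

    blocks = []
    for comp in comps:
        valid = [p for p in partitions(comp) if all(ok(b) for b in p)]
        best = min(valid, key=len)
        assert sum(1 for p in valid if len(p) == len(best)) == 1, "ambiguous oracle case"
        blocks.extend(best)
    return {frozenset(e.entry_id for e in b) for b in blocks}


class TestMergeOracle:
    def test_merge_equals_exhaustive_partition_search(self, rng):
        # replicate-cluster structure: tight groups, well separated
        for _ in range(50):
            entries = []
            n_groups = int(rng.integers(1, 5))
            centers_m = 6000 + np.cumsum(rng.uniform(5, 50, n_groups))
            centers_rt = 5 + np.cumsum(rng.uniform(2.0, 4.0, n_groups))
            k = 0
            for g in range(n_groups):
                for _ in range(int(rng.integers(1, 4))):
                    entries.append(
                        entry(
                            float(centers_m[g] + rng.uniform(-0.4, 0.4)),
                            float(centers_rt[g] + rng.uniform(-0.2, 0.2)),
                            eid=str(k),
                        )
                    )
                    k += 1
            if len(entries) > 12:
                entries = entries[:12]
            got = {
                frozenset(e.entry_id for e in f.member_entries)
                for f in merge_features(entries, 1.0, 0.5)
            }
            assert got == exhaustive_maximal_merge(entries, 1.0, 0.5)


class TestScreenRun:
    @pytest.fixture
    def clean_small(self):
        return SimulationConfig(
            seed=13, mz_jitter_sd=0.0, noise_peaks_per_spectrum=0.0, intensity_noise_sd=0.0
        )

    def planted(self, member_samples, mass=6783.0, rt=8.0):
        return PlantedToxin(
            "T1", mass, rt, 1e4, charge_states_for_mass(mass, 500, 5500), member_samples
        )

    def test_present_in_carrying_sample_absent_in_other(self, clean_small):
        toxin = self.planted({"S1": 1.0})
        truth = make_truth([toxin], n_samples=2, config=clean_small)
        features = merge_features(
            [entry(toxin.neutral_mass, toxin.rt_center, sample="S1")], 1.0, 0.5
        )
        run1 = synthesize_run(truth, "S1", clean_small)
        run2 = synthesize_run(truth, "S2", clean_small)
        (call1,) = screen_run(run1, features)
        (call2,) = screen_run(run2, features)
        assert call1.present and call1.intensity > 0
        assert abs(call1.matched_mass - toxin.neutral_mass) <= 1.0
        assert not call2.present and call2.intensity == 0.0 and call2.matched_mass is None

    def test_lowering_threshold_never_flips_present_to_absent(self, clean_small):
        toxin = self.planted({"S1": 1.0})
        truth = make_truth([toxin], config=clean_small)
        run = synthesize_run(truth, "S1", clean_small)
        features = merge_features(
            [entry(toxin.neutral_mass, toxin.rt_center, sample="S1")], 1.0, 0.5
        )
        strict = {c.feature_id for c in screen_run(run, features, detection_snr=10.0) if c.present}
        lax = {c.feature_id for c in screen_run(run, features, detection_snr=1.0) if c.present}
        assert strict <= lax

    def test_empty_feature_list_rejected(self, clean_small):
        truth = make_truth([], config=clean_small)
        run = synthesize_run(truth, "S1", clean_small)
        with pytest.raises(ValidationError):
            screen_run(run, [])
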