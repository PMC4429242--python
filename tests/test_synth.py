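"""Synthetic protocol and cohort generator."""

import hashlib
import pathlib

import numpy as np
import pytest

from pigletbrain.group import group_average, section_means
from pigletbrain.io import write_cohort
from pigletbrain.parameters import default_parameters
from pigletbrain.synth import (
    CohortVariability,
    ProtocolSpec,
    make_cohort,
    make_protocol,
)


class TestProtocol:
    def test_default_protocol_structure(self, hi_protocol):
        u, pb = hi_protocol
        assert np.allclose(u.paco2, 40.0)          # normocapnia assumed
        assert pb.edges.shape == (6,)
        assert np.all(np.diff(pb.edges) > 0)
        # occluders on during insult and titration, off elsewhere
        pre = u.t < pb.edges[1] - 1
        post = u.t >= pb.edges[3]
        assert np.allclose(u.occ[pre], 0.0)
        assert np.allclose(u.occ[post], 0.0)
        mid = (u.t >= pb.edges[1] + ProtocolSpec().onset_ramp_s) & (
            u.t < pb.edges[3] - 1)
        assert np.allclose(u.occ[mid], 1.0)
        assert u.sao2.min() == pytest.approx(ProtocolSpec().sao2_floor, abs=1e-9)

    def test_quiet_spec_has_no_insult(self):
        u, pb = make_protocol(ProtocolSpec(hi_s=0.0))
        assert np.allclose(u.occ, 0.0)
        assert np.allclose(u.sao2, u.sao2[0])
        assert pb.edges.shape == (6,)

    def test_pa_bump_then_dip(self, hi_protocol):
        """Pressure rises briefly just after insult onset, then drops below
        baseline."""
        u, pb = hi_protocol
        spec = ProtocolSpec()
        onset = pb.edges[1]
        early = (u.t > onset) & (u.t <= onset + spec.pa_bump_s)
        late = (u.t > onset + spec.pa_bump_s + spec.pa_dip_ramp_s) & (
            u.t < pb.edges[2])
        assert u.pa[early].max() > spec.pa_base
        if late.any():
            assert u.pa[late].min() < spec.pa_base - 0.5 * spec.pa_dip

    def test_titration_seeded_draw_in_range(self):
        spec = ProtocolSpec(ntp_threshold=None)
        for seed in (1, 2, 3):
            _, pb = make_protocol(spec, seed=seed)
            lo, hi = spec.titration_range
            assert lo <= pb.durations[2] <= hi

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            ProtocolSpec(baseline_s=0.0)
        with pytest.raises(ValueError):
            ProtocolSpec(sao2_floor=0.99)
        with pytest.raises(ValueError):
            ProtocolSpec(ntp_threshold=1.5)


class TestNtpClosedLoop:
    def test_insult_ends_when_ntp_reaches_threshold(self, hi_protocol,
                                                    hi_run_default):
        """The titration starts at the first sample where simulated NTP has
        fallen to ~40 % of baseline."""
        u, pb = hi_protocol
        ntp = hi_run_default.observables["ntp_frac"]
        i = np.searchsorted(u.t, pb.edges[2])
        assert ntp[i] == pytest.approx(0.40, abs=0.02)
        assert np.all(ntp[(u.t >= pb.edges[1]) & (u.t < pb.edges[2] - 60)]
                      > 0.40 - 0.02)

    def test_fallback_duration_when_threshold_unreachable(self):
        spec = ProtocolSpec(ntp_threshold=0.01, hi_s=900.0)
        _, pb = make_protocol(spec)
        assert pb.durations[1] == pytest.approx(900.0)


class TestCohort:
    def test_shapes_and_reproducibility(self, tmp_path):
        c1 = make_cohort(n=3, seed=11)
        c2 = make_cohort(n=3, seed=11)
        assert len(c1) == 3
        for rec, pb in zip(c1.records, c1.boundaries):
            assert pb.edges.shape == (6,)
            assert set(rec.signals) == {"sao2", "pa", "dHbO2", "dHHb",
                                        "doxCCO", "pH"}
        # byte-identical CSVs from the same seed
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_cohort(c1, d1)
        write_cohort(c2, d2)
        for f1 in sorted(pathlib.Path(d1).iterdir()):
            f2 = d2 / f1.name
            assert hashlib.sha256(f1.read_bytes()).hexdigest() == \
                hashlib.sha256(f2.read_bytes()).hexdigest()

    def test_zero_noise_zero_variability_gives_identical_piglets(self):
        c = make_cohort(n=3, seed=0, noise=0.0,
                        variability=CohortVariability.none())
        sect = [section_means(r, b) for r, b in zip(c.records, c.boundaries)]
        ga = group_average(sect, c.boundaries)
        for sig in ga.sd:
            sd = ga.sd[sig][np.isfinite(ga.sd[sig])]
            assert np.allclose(sd, 0.0, atol=1e-12)

    def test_cohort_sd_matches_injected_noise(self):
        """Cross-piglet SD of section means tracks the injected noise SD
        scaled by 1/sqrt(samples per section)."""
        noise_frac = 0.10
        c = make_cohort(n=15, seed=5, noise=noise_frac,
                        variability=CohortVariability.none())
        sect = [section_means(r, b) for r, b in zip(c.records, c.boundaries)]
        ga = group_average(sect, c.boundaries)
        rec, pb = c.records[0], c.boundaries[0]
        for sig in ("dHbO2", "pH"):
            clean_range = np.ptp(np.median(
                np.vstack([r.signals[sig] for r in c.records]), axis=0))
            # noise SD was frac * per-piglet range; ranges are near-common
            sigma = noise_frac * clean_range
            # phase 5 sections are widest; use phase 1 for sample count
            for phase in (0, 4):
                lo, hi = pb.window(phase)
                m = np.sum((rec.t >= lo) & (rec.t < hi)) / 10
                pred = sigma / np.sqrt(max(m, 1))
                got = np.nanmedian(ga.sd[sig][phase])
                assert got == pytest.approx(pred, rel=0.5)

    def test_all_synthetic_ph_traces_drop_and_recover(self):
        """The intracellular pH dip during the insult is present in every
        generated piglet."""
        c = make_cohort(n=5, seed=2, noise=0.0)
        for rec, pb in zip(c.records, c.boundaries):
            ph = rec.signals["pH"]
            occ = (rec.t >= pb.edges[1]) & (rec.t < pb.edges[3])
            post = rec.t >= pb.edges[4]
            base = ph[rec.t < pb.edges[1]].mean()
            assert ph[occ].min() < base - 0.03
            assert ph[post][-1] > ph[occ].min() + 0.02

    def test_ground_truth_stored(self):
        truth = default_parameters().replace(lac_n=5.0)
        c = make_cohort(n=2, seed=1, truth=truth)
        assert c.truth.lac_n == 5.0
        assert len(c.truths) == 2

    def test_too_small_cohort_rejected(self):
        with pytest.raises(ValueError):
            make_cohort(n=1, seed=0)
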