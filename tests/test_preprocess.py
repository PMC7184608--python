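import numpy as np
import pytest

from dfhm.preprocess import (
    PipelineOrderError,
    RankError,
    RejectionCriteria,
    bandpass,
    decompose_ica,
    reject_artifacts,
    require_preprocessed,
    surface_laplacian,
    to_average_reference,
)
from dfhm.synthetic import BLINK_AMPLITUDE_UV, inject_artifacts

from conftest import make_recording


def sinusoid_recording(montage, freq, duration=4.0, fs=500.0, amp=1.0):
    t = np.arange(int(duration * fs)) / fs
    x = amp * np.sin(2 * np.pi * freq * t)
    return make_recording(np.tile(x, (montage.n_channels, 1)), montage, fs)


def steady(x, fs, order=100):
    """Drop the filter-length edge transients before comparing."""
    k = order
    return x[..., k:-k]


class TestBandpass:
    def test_passband_preserves_10hz(self, montage):
        rec = sinusoid_recording(montage, 10.0)
        out = bandpass(rec)
        rms_in = np.sqrt((steady(rec.samples[0], 500.0) ** 2).mean())
        rms_out = np.sqrt((steady(out.samples[0], 500.0) ** 2).mean())
        assert rms_out == pytest.approx(rms_in, rel=0.05)

    def test_dc_removed(self, montage):
        rec = make_recording(np.full((montage.n_channels, 2000), 5.0), montage)
        out = bandpass(rec)
        assert np.abs(steady(out.samples, 500.0)).max() < 0.05 * 5.0

    def test_50hz_attenuated(self, montage):
        rec = sinusoid_recording(montage, 50.0)
        out = bandpass(rec)
        p_in = (steady(rec.samples[0], 500.0) ** 2).mean()
        p_out = (steady(out.samples[0], 500.0) ** 2).mean()
        assert p_out <= 0.01 * p_in

    def test_invalid_band_edges(self, montage):
        rec = sinusoid_recording(montage, 10.0)
        with pytest.raises(ValueError):
            bandpass(rec, low=0.5, high=300.0)
        with pytest.raises(ValueError):
            bandpass(rec, low=-1.0, high=40.0)

    def test_provenance_flags_transient(self, montage):
        out = bandpass(sinusoid_recording(montage, 10.0))
        assert any("edge_transient" in step for step in out.provenance)


class TestICA:
    def test_roundtrip_identity(self, clean_recording):
        rec = bandpass(clean_recording)
        dec = decompose_ica(rec, seed=0)
        rms = np.sqrt((rec.samples**2).mean())
        assert np.abs(dec.reconstruct() - rec.samples).max() < 1e-6 * rms

    def test_seed_determinism(self, clean_recording):
        rec = bandpass(clean_recording)
        a = decompose_ica(rec, seed=3)
        b = decompose_ica(rec, seed=3)
        np.testing.assert_array_equal(a.mixing, b.mixing)
        np.testing.assert_array_equal(a.sources, b.sources)

    def test_blink_source_recovered_in_toy_mixture(self, toy_montage):
        """A 3-channel mixture of a 6 Hz sinusoid and a blink train yields a
        component whose time course correlates > 0.95 with the blink train."""
        fs, dur = 500.0, 20.0
        t = np.arange(int(dur * fs)) / fs
        rng = np.random.default_rng(0)
        sine = np.sin(2 * np.pi * 6.0 * t)
        blink = np.zeros_like(t)
        for onset in np.arange(1.0, dur - 1.0, 2.5):
            i0, i1 = int(onset * fs), int((onset + 0.2) * fs)
            blink[i0:i1] = np.sin(2 * np.pi * np.arange(i1 - i0) / (i1 - i0))
        A = np.array([[1.0, 8.0], [0.8, 1.0], [1.2, 0.1]])
        X = A @ np.vstack([sine, blink]) + 0.01 * rng.standard_normal((3, t.size))
        rec = make_recording(X, toy_montage, fs)
        dec = decompose_ica(rec, seed=1)
        corrs = [abs(np.corrcoef(s, blink)[0, 1]) for s in dec.sources]
        assert max(corrs) > 0.95

    def test_duplicated_channels_raise_rank_error(self, montage):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((25, 2000))
        x[1] = x[0]  # duplicate channel
        rec = make_recording(x, montage)
        with pytest.raises(RankError, match="duplicated"):
            decompose_ica(rec, seed=0)

    def test_too_short_recording_rejected(self, montage):
        rec = make_recording(np.random.default_rng(0).standard_normal((25, 100)), montage)
        with pytest.raises(ValueError, match="samples"):
            decompose_ica(rec, seed=0)


@pytest.fixture(scope="module")
def blink_setup(clean_recording):
    dirty, log = inject_artifacts(clean_recording, 6.0, seed=7)
    bp = bandpass(dirty)
    dec = decompose_ica(bp, seed=0)
    cleaned = reject_artifacts(bp, dec)
    return bp, dec, cleaned, log


class TestRejectArtifacts:
    def test_frontal_rms_reduced_in_artifact_windows(self, blink_setup, clean_recording):
        bp, dec, cleaned, log = blink_setup
        m = clean_recording.montage
        fs = clean_recording.sample_rate
        fi = m.indices(m.frontal_set)
        inside = np.zeros(clean_recording.n_times, dtype=bool)
        for ev in log:
            i0 = int(ev["onset"] * fs)
            inside[i0:i0 + int(ev["duration"] * fs)] = True
        rms = lambda s, mask: np.sqrt((s[np.ix_(fi, np.where(mask)[0])] ** 2).mean())
        assert rms(cleaned.samples, inside) <= 0.5 * rms(bp.samples, inside)
        outside_change = abs(rms(cleaned.samples, ~inside) / rms(bp.samples, ~inside) - 1)
        assert outside_change <= 0.10

    def test_removed_energy_concentrates_in_artifact_windows(self, blink_setup, clean_recording):
        bp, dec, cleaned, log = blink_setup
        fs = clean_recording.sample_rate
        inside = np.zeros(clean_recording.n_times, dtype=bool)
        for ev in log:
            i0 = int(ev["onset"] * fs)
            inside[i0:i0 + int(ev["duration"] * fs)] = True
        removed = bp.samples - cleaned.samples
        energy = (removed**2).sum(axis=0)
        assert energy[inside].sum() / energy.sum() >= 0.70

    def test_no_rejection_equals_roundtrip(self, clean_recording):
        bp = bandpass(clean_recording)
        dec = decompose_ica(bp, seed=0)
        # impossible criteria: nothing can exceed |r| > 1
        out = reject_artifacts(bp, dec, RejectionCriteria(corr_threshold=1.1))
        np.testing.assert_allclose(out.samples, dec.reconstruct(), atol=1e-9)
        assert dec.rejected_components == set()

    def test_degenerate_criteria_refused(self, clean_recording):
        bp = bandpass(clean_recording)
        dec = decompose_ica(bp, seed=0)
        with pytest.raises(ValueError, match="every component"):
            reject_artifacts(bp, dec, RejectionCriteria(corr_threshold=0.0))

    def test_foreign_decomposition_rejected(self, clean_recording):
        bp = bandpass(clean_recording)
        dec = decompose_ica(bp, seed=0)
        with pytest.raises(ValueError, match="not fitted"):
            reject_artifacts(clean_recording, dec)


class TestSurfaceLaplacian:
    def test_uniform_field_maps_to_zero(self, montage):
        rec = make_recording(np.full((25, 100), 5.0), montage)
        out = surface_laplacian(rec)
        np.testing.assert_allclose(out.samples, 0.0, atol=1e-12)

    def test_hand_computed_chain(self, toy_montage):
        rec = make_recording(np.array([[0.0], [3.0], [0.0]]), toy_montage)
        out = surface_laplacian(rec)
        np.testing.assert_allclose(out.samples[:, 0], [-3.0, 3.0, -3.0])

    def test_not_idempotent(self, montage):
        rng = np.random.default_rng(2)
        rec = make_recording(rng.standard_normal((25, 200)), montage)
        once = surface_laplacian(rec)
        twice = surface_laplacian(once)
        assert not np.allclose(once.samples, twice.samples)

    def test_linearity(self, montage):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((25, 300))
        y = rng.standard_normal((25, 300))
        a, b = 2.5, -1.3
        lhs = surface_laplacian(make_recording(a * x + b * y, montage)).samples
        rhs = (
            a * surface_laplacian(make_recording(x, montage)).samples
            + b * surface_laplacian(make_recording(y, montage)).samples
        )
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)


class TestAverageReference:
    def test_zero_column_means(self, clean_recording):
        out = to_average_reference(clean_recording)
        assert np.abs(out.samples.mean(axis=0)).max() < 1e-10
        assert out.reference_state == "average"

    def test_idempotent(self, clean_recording):
        once = to_average_reference(clean_recording)
        twice = to_average_reference(once)
        np.testing.assert_array_equal(once.samples, twice.samples)

    def test_common_mode_invariance(self, montage):
        rng = np.random.default_rng(4)
        x = rng.standard_normal((25, 100))
        a = to_average_reference(make_recording(x, montage))
        b = to_average_reference(make_recording(x + 7.0, montage))
        np.testing.assert_allclose(a.samples, b.samples, atol=1e-12)

    def test_single_channel_rejected(self):
        class OneChannel:
            n_channels = 1
            reference_state = "original"

        with pytest.raises(ValueError):
            to_average_reference(OneChannel())


class TestPipelineOrderContract:
    def test_canonical_chain_passes(self, clean_recording):
        rec = bandpass(clean_recording)
        dec = decompose_ica(rec, seed=0)
        rec = reject_artifacts(rec, dec, RejectionCriteria(corr_threshold=1.1))
        rec = to_average_reference(surface_laplacian(rec))
        require_preprocessed(rec)  # does not raise

    def test_out_of_order_chain_raises(self, clean_recording):
        rec = surface_laplacian(bandpass(clean_recording))
        rec = to_average_reference(rec)
        with pytest.raises(PipelineOrderError):
            require_preprocessed(rec)
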