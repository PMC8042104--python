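"""Conversion-factor fit, absolute conversion, detection limits, mass."""
import math

import numpy as np
import pandas as pd
import pytest

from embryoquant import (
    AbsoluteQuantModel,
    SpikeInTable,
    detection_limit_transcripts,
    fit_conversion_factor,
    to_absolute,
    transcripts_to_mass,
    volume_scaled_mass,
)
from embryoquant.calibration import rna_molecular_weight, round_sig
from embryoquant.io import AVOGADRO, ValidationError
from embryoquant.relative import RelativeExpressionMatrix


def _rel_frame(values, index, columns=("s1",)):
    return pd.DataFrame(values, index=list(index), columns=list(columns))


def irls_poisson_offset_intercept(r, offset_log, tol=1e-12, max_iter=200):
    """Independent IRLS oracle for the intercept-only Poisson log-link GLM.

    Newton-Raphson on the log-likelihood l(b) = sum(r*(b+o) - exp(b+o)):
    score = sum(r) - sum(exp(b+o)), info = sum(exp(b+o)).
    """
    beta = 0.0
    for _ in range(max_iter):
        mu = np.exp(beta + offset_log)
        step = (r.sum() - mu.sum()) / mu.sum()
        beta += step
        if abs(step) < tol:
            return beta
    raise RuntimeError("IRLS did not converge")


class TestConversionFactor:
    def test_closed_form_on_three_spike_example(self):
        rel = _rel_frame([[0.01], [0.1], [1.0]], ["ERCC-a", "ERCC-b", "ERCC-c"])
        spikes = SpikeInTable({"ERCC-a": 100.0, "ERCC-b": 1000.0, "ERCC-c": 10000.0})
        cf = fit_conversion_factor(rel, spikes)
        assert cf.beta["s1"] == pytest.approx(math.log(1.11 / 11100))
        assert cf.scale["s1"] == pytest.approx(10000.0)

    def test_equal_relative_and_known_gives_identity(self):
        vals = [[3.0], [7.0], [11.0]]
        ids = ["ERCC-a", "ERCC-b", "ERCC-c"]
        cf = fit_conversion_factor(
            _rel_frame(vals, ids), SpikeInTable(dict(zip(ids, [3.0, 7.0, 11.0])))
        )
        assert cf.beta["s1"] == pytest.approx(0.0, abs=1e-15)
        assert cf.scale["s1"] == pytest.approx(1.0)

    def test_zero_count_spikes_stay_in_the_sums(self):
        ids = ["ERCC-a", "ERCC-b"]
        cf = fit_conversion_factor(
            _rel_frame([[1.0], [0.0]], ids), SpikeInTable(dict(zip(ids, [10.0, 90.0])))
        )
        assert cf.scale["s1"] == pytest.approx(100.0)  # (10+90)/1, not 10/1

    def test_all_zero_spikes_is_an_error(self):
        ids = ["ERCC-a", "ERCC-b"]
        with pytest.raises(ValidationError, match="no spike-in signal"):
            fit_conversion_factor(
                _rel_frame([[0.0], [0.0]], ids),
                SpikeInTable(dict(zip(ids, [1.0, 2.0]))),
            )

    def test_unknown_spike_id_is_listed(self):
        with pytest.raises(ValidationError, match="ERCC-mystery"):
            fit_conversion_factor(
                _rel_frame([[1.0]], ["ERCC-mystery"]), SpikeInTable({"ERCC-a": 1.0})
            )

    def test_matches_irls_oracle_on_random_instances(self):
        rng = np.random.default_rng(2024)
        for _ in range(20):
            n = 20
            s = np.exp(rng.uniform(np.log(1e2), np.log(1e7), n))
            r = rng.gamma(2.0, 2.0, n) * 1e-4 * s
            ids = [f"ERCC-{i}" for i in range(n)]
            cf = fit_conversion_factor(
                _rel_frame(r[:, None], ids), SpikeInTable(dict(zip(ids, s)))
            )
            oracle = irls_poisson_offset_intercept(r, np.log(s))
            assert cf.beta["s1"] == pytest.approx(oracle, abs=1e-8)

    def test_shift_property(self):
        """Scaling all relative abundances by c shifts beta by exactly log c."""
        rng = np.random.default_rng(5)
        s = np.exp(rng.uniform(5, 15, 30))
        r = rng.gamma(2.0, 1.0, 30) * 1e-3 * s
        ids = [f"ERCC-{i}" for i in range(30)]
        table = SpikeInTable(dict(zip(ids, s)))
        b1 = fit_conversion_factor(_rel_frame(r[:, None], ids), table).beta["s1"]
        c = 7.3
        b2 = fit_conversion_factor(_rel_frame(c * r[:, None], ids), table).beta["s1"]
        assert b2 - b1 == pytest.approx(math.log(c), abs=1e-12)


class TestAbsoluteConversion:
    def test_arithmetic_and_zero(self, fitted):
        # rho = 0.5 at scale 10,000 -> 5,000 transcripts per embryo
        assert 0.5 * 10000 == 5000
        zero_rho = (fitted.relative.genes() == 0).to_numpy()
        assert (fitted.absolute.genes.to_numpy()[zero_rho] == 0).all()

    def test_round_trip_recovers_rpg10k_to_float_precision(self, fitted):
        back = fitted.absolute.genes / fitted.conversion_factors.scale
        np.testing.assert_array_almost_equal_nulp(
            back.to_numpy(), fitted.relative.genes().to_numpy(), nulp=1
        )

    def test_missing_sample_factor_is_an_error(self, fitted, default_sim):
        cf = fitted.conversion_factors
        truncated = type(cf)(cf.table.iloc[:-1])
        with pytest.raises(ValidationError, match="conversion factor"):
            to_absolute(fitted.relative, truncated)


class TestDetectionLimit:
    def test_limit_from_scale(self, fitted):
        cf = fitted.conversion_factors
        fake = type(cf)(
            pd.DataFrame(
                {"beta": [-math.log(111000.0)], "scale": [111000.0],
                 "n_spikes_used": [92]},
                index=["s1"],
            )
        )
        limits, mean = detection_limit_transcripts(fake, 0.01)
        assert limits["s1"] == pytest.approx(1110.0)
        assert mean == pytest.approx(1110.0)

    def test_zero_threshold_and_linearity(self, fitted):
        cf = fitted.conversion_factors
        zero, _ = detection_limit_transcripts(cf, 0.0)
        assert (zero == 0).all()
        one, _ = detection_limit_transcripts(cf, 0.01)
        three, _ = detection_limit_transcripts(cf, 0.03)
        assert np.allclose(three, 3 * one)


class TestMassConversion:
    def test_hand_computed_example(self):
        # L = 1000 nt -> MW = 320,659 g/mol; 1e9 molecules -> 0.5325 ng
        assert rna_molecular_weight(1000) == pytest.approx(320659.0)
        mass_ng = 1e9 * 320659.0 / AVOGADRO * 1e9
        assert mass_ng == pytest.approx(0.5325, abs=5e-5)

    def test_zero_and_linearity(self, fitted, default_sim):
        mass, totals = transcripts_to_mass(fitted.absolute, default_sim.models)
        zero = (fitted.absolute.genes == 0).to_numpy()
        assert (mass.to_numpy()[zero] == 0).all()
        doubled = fitted.absolute
        doubled_genes = doubled.genes * 2
        import dataclasses

        doubled = dataclasses.replace(doubled, genes=doubled_genes)
        _, totals2 = transcripts_to_mass(doubled, default_sim.models)
        assert np.allclose(totals2, 2 * totals)

    def test_missing_gene_errors_or_skips(self, fitted, default_sim):
        import dataclasses

        renamed = fitted.absolute.genes.rename(index={"gene0001": "ghost"})
        broken = dataclasses.replace(fitted.absolute, genes=renamed)
        with pytest.raises(ValidationError, match="ghost"):
            transcripts_to_mass(broken, default_sim.models)
        with pytest.warns(UserWarning, match="skipping"):
            mass, _ = transcripts_to_mass(broken, default_sim.models, permissive=True)
        assert "ghost" not in mass.index

    def test_total_mass_shows_dip_and_rebound(self, fitted, default_sim):
        """The configured global poly(A) dip at 2 h and rebound at 3 h."""
        _, totals = transcripts_to_mass(fitted.absolute, default_sim.models)
        t = totals.to_numpy()
        assert t[1] < t[0]  # dip at 2 h
        assert t[2] > 2 * t[1]  # strong rebound at 3 h


class TestVolumeScaling:
    def test_worked_example_volume_ratio(self):
        res = volume_scaled_mass(1.26, source_volume_mm3=0.025, target_volume_mm3=0.268)
        assert res.volume_ratio_3sig == pytest.approx(10.7)
        assert res.scaled_mass_ng_3sig == pytest.approx(13.5)

    def test_equal_volumes_identity(self):
        res = volume_scaled_mass(2.5, 0.1, 0.1)
        assert res.scaled_mass_ng == 2.5
        assert res.volume_ratio == 1.0

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(ValidationError):
            volume_scaled_mass(1.0, 0.0, 1.0)

    def test_round_sig(self):
        assert round_sig(10.72, 3) == 10.7
        assert round_sig(13.5072, 3) == 13.5
        assert round_sig(0.0, 3) == 0.0


class TestModelSurface:
    def test_from_files_matches_in_memory_fit(self, tmp_path, small_sim):
        from embryoquant import write_fixture

        paths = write_fixture(small_sim, tmp_path)
        model = AbsoluteQuantModel.from_files(
            paths["counts.tsv"],
            paths["spikes.tsv"],
            models_path=paths["models.gff3"],
            samples_path=paths["samples.tsv"],
        )
        res_files = model.fit()
        res_mem = AbsoluteQuantModel(
            small_sim.counts, small_sim.spikes, small_sim.models
        ).fit()
        pd.testing.assert_frame_equal(
            res_files.conversion_factors.table,
            res_mem.conversion_factors.table,
            check_names=False,
        )
        pd.testing.assert_frame_equal(
            res_files.absolute.genes, res_mem.absolute.genes, check_names=False
        )

    def test_summary_lists_every_sample(self, fitted):
        text = fitted.summary()
        for s in fitted.relative.samples:
            assert s.sample_id in text
        assert "mean detection limit" in text
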