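"""Concentration sweeps, CSV export and the argv front end."""

import json

import numpy as np
import pandas as pd
import pytest

from apblock.biomarkers import AbnormalityCode
from apblock.doseresponse import ChannelBlockSpec, ChannelId, CompoundSpec
from apblock.engine import PacingProtocol, pace_to_steady
from apblock.cellmodels import get_model, apply_block
from apblock.doseresponse import block_factors
from apblock.study import (
    ConcentrationRange,
    compound_from_config,
    concentration_grid,
    export_csv,
    load_config,
    main,
    run_study,
    summary_frame,
)

FAST = dict(max_paces=300)


def fast_protocol(model, **kw):
    return PacingProtocol.for_model(model, frequency=1.0, max_paces=300, **kw)


@pytest.fixture(scope="module")
def herg_study(demo_model):
    compound = CompoundSpec("hERG blocker",
                            (ChannelBlockSpec(ChannelId.IKr, 6.0),))
    return run_study("sixcurrent_demo", compound,
                     ConcentrationRange(0.1, 100.0, 4),
                     fast_protocol(demo_model))


class TestConcentrationGrid:
    @pytest.mark.parametrize(
        "rng, expected",
        [
            (ConcentrationRange(0.1, 100, 4, log_spaced=True),
             [0.0, 0.1, 1.0, 10.0, 100.0]),
            (ConcentrationRange(5, 5, 1), [0.0, 5.0]),
            (ConcentrationRange(1, 3, 3, log_spaced=False),
             [0.0, 1.0, 2.0, 3.0]),
        ],
    )
    def test_grids(self, rng, expected):
        assert concentration_grid(rng) == pytest.approx(expected)

    def test_endpoints_exact(self):
        g = concentration_grid(ConcentrationRange(0.3, 77.7, 9))
        assert g[0] == 0.0 and g[1] == 0.3 and g[-1] == 77.7

    def test_log_requires_positive_low(self):
        with pytest.raises(ValueError, match="low"):
            ConcentrationRange(0.0, 10.0, 3, log_spaced=True)

    def test_bad_count(self):
        with pytest.raises(ValueError):
            ConcentrationRange(1.0, 10.0, 0)


class TestRunStudy:
    def test_control_row_first_and_zero_delta(self, herg_study):
        rows = herg_study.rows
        assert rows[0].conc == 0.0
        assert rows[0].delta_apd90_pct == 0.0
        assert [r.conc for r in rows] == sorted(r.conc for r in rows)

    def test_ikr_block_prolongs_monotonically(self, herg_study):
        deltas = [r.delta_apd90_pct for r in herg_study.rows
                  if r.delta_apd90_pct is not None]
        assert len(deltas) >= 3
        assert all(b > a for a, b in zip(deltas, deltas[1:]))

    def test_high_block_flags_failure_with_absent_delta(self, herg_study):
        top = herg_study.rows[-1]
        codes = {m.code for m in top.messages}
        assert codes & {AbnormalityCode.REPOLARISATION_FAILURE,
                        AbnormalityCode.ALTERNANS}
        assert top.delta_apd90_pct is None
        assert top.biomarkers.apd90 is None

    def test_empty_compound_reproduces_control(self, demo_model):
        res = run_study("sixcurrent_demo", CompoundSpec("inert"),
                        ConcentrationRange(1.0, 10.0, 2),
                        fast_protocol(demo_model))
        for row in res.rows:
            assert row.delta_apd90_pct == pytest.approx(0.0, abs=0.1)
            assert row.messages == ()
            assert row.converged

    def test_warm_start_equivalence(self, demo_model, control_steady):
        """Cold-starting a drug run from model defaults instead of the
        control steady state changes APD90 by < 1 ms."""
        from apblock.biomarkers import compute_biomarkers

        factors = block_factors(
            CompoundSpec("x", (ChannelBlockSpec(ChannelId.IKr, 6.0),)), 1.0)
        params = apply_block(demo_model, demo_model.default_parameters,
                             factors)
        proto = fast_protocol(demo_model)
        warm = pace_to_steady(demo_model, params, proto,
                              control_steady.end_state)
        cold = pace_to_steady(demo_model, params, proto)
        a = compute_biomarkers(warm.final_trace).apd90
        b = compute_biomarkers(cold.final_trace).apd90
        assert abs(a - b) < 1.0

    def test_metadata_echoes_inputs(self, herg_study):
        md = herg_study.metadata
        assert md["model"] == "sixcurrent_demo"
        assert md["compound"]["blocks"][0]["channel"] == "IKr"
        assert md["pacing"]["abs_tol"] == 1e-6
        assert md["pacing"]["rel_tol"] == 1e-8


class TestExportCsv:
    def test_file_set_and_row_count(self, herg_study, tmp_path):
        files = export_csv(herg_study, tmp_path)
        df = pd.read_csv(tmp_path / "summary.csv")
        assert len(df) == 5  # control + 4
        assert (tmp_path / "metadata.json").exists()
        traces = [f for f in files if f.name.startswith("trace_")]
        assert len(traces) == 5

    def test_reexport_byte_identical(self, herg_study, tmp_path):
        export_csv(herg_study, tmp_path / "a")
        export_csv(herg_study, tmp_path / "b")
        assert ((tmp_path / "a" / "summary.csv").read_bytes()
                == (tmp_path / "b" / "summary.csv").read_bytes())

    def test_absent_apd90_is_empty_cell_with_message(self, herg_study,
                                                     tmp_path):
        export_csv(herg_study, tmp_path)
        df = pd.read_csv(tmp_path / "summary.csv")
        top = df.iloc[-1]
        assert np.isnan(top["apd90_ms"])
        assert "REPOLARISATION_FAILURE" in str(top["messages"])

    def test_summary_columns(self, herg_study):
        df = summary_frame(herg_study)
        for col in ("conc_uM", "factor_IKr", "factor_Ito", "apd90_ms",
                    "delta_apd90_pct", "converged", "paces_run", "messages"):
            assert col in df.columns

    def test_metadata_json_loads(self, herg_study, tmp_path):
        export_csv(herg_study, tmp_path)
        md = json.loads((tmp_path / "metadata.json").read_text())
        assert md["concentrations_uM"][0] == 0.0


class TestMain:
    def test_happy_path(self, tmp_path):
        rc = main([
            "--model", "sixcurrent_demo", "--pacing-freq", "1",
            "--pic50-herg", "6", "--plasma-conc-low", "0.1",
            "--plasma-conc-high", "10", "--plasma-conc-count", "2",
            "--output", str(tmp_path / "out"),
        ])
        assert rc == 0
        assert (tmp_path / "out" / "summary.csv").exists()

    def test_end_to_end_determinism(self, tmp_path):
        args = ["--pic50-herg", "5.5", "--plasma-conc-low", "1",
                "--plasma-conc-high", "10", "--plasma-conc-count", "2"]
        assert main(args + ["--output", str(tmp_path / "a")]) == 0
        assert main(args + ["--output", str(tmp_path / "b")]) == 0
        assert ((tmp_path / "a" / "summary.csv").read_bytes()
                == (tmp_path / "b" / "summary.csv").read_bytes())

    def test_malformed_pic50_is_usage_error(self, capsys):
        assert main(["--pic50-herg", "notanumber"]) == 2

    def test_unknown_model_is_usage_error(self, capsys):
        assert main(["--model", "no_such_model"]) == 2
        assert "sixcurrent_demo" in capsys.readouterr().out

    def test_hill_without_potency_rejected(self):
        assert main(["--hill-herg", "2"]) == 2

    def test_list_models(self, capsys):
        assert main(["--list-models"]) == 0
        assert "sixcurrent_demo" in capsys.readouterr().out

    def test_config_file(self, tmp_path):
        cfg = tmp_path / "study.yaml"
        cfg.write_text(
            "model: sixcurrent_demo\n"
            "pacing_frequency_hz: 1.0\n"
            "compound:\n"
            "  name: config compound\n"
            "  channels:\n"
            "    hERG: {pic50: 6.0}\n"
            "    CaV1.2: {ic50_uM: 10.0, hill: 1.2}\n"
            "concentrations: {low_uM: 1, high_uM: 10, count: 2}\n"
        )
        compound = compound_from_config(load_config(cfg))
        assert compound.name == "config compound"
        channels = {b.channel for b in compound.blocks}
        assert channels == {ChannelId.IKr, ChannelId.ICaL}
        cal = next(b for b in compound.blocks
                   if b.channel is ChannelId.ICaL)
        assert cal.pic50 == pytest.approx(5.0)
        assert cal.hill == 1.2
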