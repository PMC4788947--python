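"""Workbench tests: config validation, persistence, SBML export, fixtures, CLI."""

import json
import xml.etree.ElementTree as ET

import numpy as np
import pytest

import moodkit as mk
from moodkit.config import RunConfig, load_config, save_config
from moodkit.errors import ConfigError
from moodkit.fixtures import FixtureSpec, make_fixture
from moodkit.io import persist_results, read_pareto, read_table, write_pareto
from moodkit.sbml import SBML_NS, SPECIES_IDS

from conftest import make_tiny_pareto


class TestConfig:
    def test_empty_file_yields_characterized_defaults(self, tmp_path):
        path = tmp_path / "empty.yaml"
        path.write_text("")
        cfg = load_config(path)
        assert cfg.base_params().kd == 0.06          # inducer diffusion rate
        assert cfg.base_params().dmA == 0.3624
        assert cfg.moo.max_evals == 15000
        assert cfg.box.j1 == (1e-3, 200.0)

    def test_no_file_equals_defaults(self):
        assert load_config(None) == RunConfig()

    def test_reversed_bounds_error_names_parameter(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text("bounds:\n  dB: [0.3, 0.01]\n")
        with pytest.raises(ConfigError, match="dB"):
            load_config(path)

    def test_unknown_key_rejected(self, tmp_path):
        path = tmp_path / "typo.yaml"
        path.write_text("protocoll:\n  tf: 100\n")
        with pytest.raises(ConfigError):
            load_config(path)

    def test_unknown_kinetic_parameter_rejected(self, tmp_path):
        path = tmp_path / "bad2.yaml"
        path.write_text("parameters:\n  kx_unknown: 3\n")
        with pytest.raises(ConfigError):
            load_config(path)

    def test_round_trip(self, tmp_path):
        cfg = RunConfig(seed=7, parameters={"kd": 0.08},
                        bounds={"dB": (0.02, 0.2)})
        path = tmp_path / "cfg.yaml"
        save_config(cfg, path)
        assert load_config(path) == cfg

    def test_hash_tracks_settings(self):
        a, b = RunConfig(), RunConfig(seed=1)
        assert a.config_hash() != b.config_hash()
        assert a.config_hash() == RunConfig().config_hash()

    def test_malformed_yaml(self, tmp_path):
        path = tmp_path / "broken.yaml"
        path.write_text("a: [unclosed\n")
        with pytest.raises(ConfigError):
            load_config(path)


class TestPersistence:
    def test_pareto_round_trip_machine_precision(self, tmp_path, tiny_pareto):
        path = tmp_path / "pareto.csv"
        write_pareto(tiny_pareto, path)
        back = read_pareto(path)
        assert np.array_equal(back.front(), tiny_pareto.front())
        assert np.array_equal(back.thetas(), tiny_pareto.thetas())

    def test_schema_tag_present(self, tmp_path, tiny_pareto):
        path = tmp_path / "pareto.csv"
        write_pareto(tiny_pareto, path)
        assert path.read_text().startswith("# schema: pareto-v1")
        assert len(read_table(path)) == len(tiny_pareto)

    def test_manifest_enumerates_files(self, tmp_path, tiny_pareto):
        ld_table = mk.export_ld(tiny_pareto.front(), tiny_pareto.thetas())
        manifest = persist_results(tmp_path, seed=3, config_hash="abc",
                                   pareto=tiny_pareto, ld_table=ld_table)
        for fname in manifest["files"].values():
            assert (tmp_path / fname).exists()
        disk = json.loads((tmp_path / "manifest.json").read_text())
        assert disk == manifest
        assert disk["seed"] == 3

    def test_unwritable_directory(self, tiny_pareto):
        with pytest.raises(ConfigError):
            persist_results("/proc/nope", seed=0, config_hash="x",
                            pareto=tiny_pareto)


class TestSbmlExport:
    def test_document_structure(self, tmp_path, params):
        path = mk.export_sbml(params, tmp_path / "model.xml")
        root = ET.parse(path).getroot()
        species = root.findall(f".//{{{SBML_NS}}}species")
        assert len(species) == len(SPECIES_IDS) == 10
        assert {s.get("id") for s in species} == set(SPECIES_IDS)
        assert len(root.findall(f".//{{{SBML_NS}}}rateRule")) == 9
        assert len(root.findall(f".//{{{SBML_NS}}}assignmentRule")) == 1
        assert root.get("level") == "3" and root.get("version") == "1"

    def test_initial_concentrations_are_baseline(self, tmp_path, params):
        path = mk.export_sbml(params, tmp_path / "model.xml")
        root = ET.parse(path).getroot()
        by_id = {s.get("id"): float(s.get("initialConcentration"))
                 for s in root.findall(f".//{{{SBML_NS}}}species")}
        assert by_id["x1"] == pytest.approx(params.kmA_CgA / params.dmA)
        assert by_id["x3"] == 0.0

    def test_invalid_path_raises(self, params):
        with pytest.raises(OSError):
            mk.export_sbml(params, "/nonexistent-dir/model.xml")


class TestFixtures:
    def test_benchmark_front_example(self):
        problem = make_fixture(FixtureSpec(kind="benchmark"))
        # theta = 1 sits on the front at (1, 1)
        assert problem(np.array([1.0])).J == (1.0, 1.0)
        assert problem.true_front(1.0) == 1.0

    def test_seed_determinism(self):
        a = make_fixture(FixtureSpec(kind="planted", seed=5))
        b = make_fixture(FixtureSpec(kind="planted", seed=5))
        assert np.array_equal(a.front, b.front)
        assert np.array_equal(a.theta, b.theta)

    def test_zero_shift_rarely_significant(self):
        """Null planted data: the cluster count stays small and significant
        parameters are rare (Bonferroni holds the family-wise rate)."""
        from moodkit.guidelines import cluster_tree, select_k

        n_sig = []
        for seed in range(10):
            d = make_fixture(FixtureSpec(kind="planted", seed=seed, effect=0.0))
            res = select_k(cluster_tree(d.front), d.theta, names=list(d.names))
            tab = res.table[res.table.k == res.k]
            n_sig.append(int(tab["significant"].sum()))
        assert sum(c == 0 for c in n_sig) >= 8

    def test_unknown_kind_rejected(self):
        with pytest.raises(ConfigError):
            make_fixture(FixtureSpec(kind="nope"))


class TestCli:
    @pytest.fixture()
    def runner(self):
        from click.testing import CliRunner

        return CliRunner()

    @pytest.fixture()
    def outdir(self, tmp_path):
        pareto = make_tiny_pareto(n=10, seed=4)
        write_pareto(pareto, tmp_path / "pareto.csv")
        return tmp_path

    def test_simulate_writes_trajectory(self, runner, tmp_path):
        from moodkit.cli import main

        result = runner.invoke(main, ["simulate", "--outdir", str(tmp_path)])
        assert result.exit_code == 0, result.output
        assert (tmp_path / "trajectory.csv").exists()

    def test_guidelines_and_leveldiagram(self, runner, outdir):
        from moodkit.cli import main

        r1 = runner.invoke(main, ["guidelines", "--outdir", str(outdir)])
        assert r1.exit_code == 0, r1.output
        assert (outdir / "guidelines.csv").exists()
        r2 = runner.invoke(main, ["leveldiagram", "--outdir", str(outdir)])
        assert r2.exit_code == 0, r2.output
        assert (outdir / "ld.csv").exists()

    def test_export_sbml(self, runner, tmp_path):
        from moodkit.cli import main

        result = runner.invoke(main, ["export-sbml", "--outdir", str(tmp_path)])
        assert result.exit_code == 0, result.output
        assert (tmp_path / "model.xml").exists()

    def test_error_exits_nonzero(self, runner, tmp_path):
        from moodkit.cli import main

        bad = tmp_path / "bad.yaml"
        bad.write_text("bounds:\n  dB: [0.3, 0.01]\n")
        result = runner.invoke(
            main, ["guidelines", "--config", str(bad), "--outdir", str(tmp_path)]
        )
        assert result.exit_code == 1
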