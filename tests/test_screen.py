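"""End-to-end screen model, file pipeline and CLI."""

import json
from pathlib import Path

import numpy as np
import pytest
import yaml
from click.testing import CliRunner

from repeatcc import peptides_synthetic as pep
from repeatcc.cli import main as cli_main
from repeatcc.coiledcoil import write_track
from repeatcc.records import ProteinRecord, SequenceError, read_fasta, write_fasta
from repeatcc.screen import ProteomeScreen, RunConfig, run_design, run_screen
from repeatcc.simulate import (
    CCPlantSpec,
    ProteomeSpec,
    generate_cc_tracks,
    generate_proteome,
)


class TestProteomeScreenModel:
    def test_fit_summary_and_metrics(self, small_proteome, planted_cc):
        _, records, _ = small_proteome
        _, tracks, _ = planted_cc
        model = ProteomeScreen(records, tracks=tracks, species="syn")
        res = model.fit()
        s = res.summary_counts
        assert s.n_proteins == len(records)
        assert 0 <= s.percent("Q4") <= 100
        text = res.summary()
        assert "Q4" in text and "overlap" in text

    @staticmethod
    def _overlap_testbed(bias, seed):
        # short proteins with long repeats/segments so the relative-length
        # expected overlap straddles the 4-residue dichotomy
        spec = ProteomeSpec(
            n_proteins=500, length_log_mean=5.3, length_log_sd=0.3,
            p_Q4=0.4, p_A4=0.4, p_QA4=0.1, cooccurrence_factor=1.0,
            repeat_len_geom_p=0.12, seed=seed,
        )
        records, truth = generate_proteome(spec)
        plant = CCPlantSpec(
            p_cc=0.8, seg_len_min=30, seg_len_max=60,
            overlap_bias=bias, seed=seed + 1,
        )
        tracks, _ = generate_cc_tracks(records, truth, plant)
        return ProteomeScreen(records, tracks=tracks).fit().overlap_tests["all"]

    def test_planted_overlap_bias_enriches_overlap(self):
        """CC segments planted on repeats give observed >> expected overlap,
        and the enrichment grows with the planted bias."""
        null = self._overlap_testbed(bias=0.0, seed=21)
        half = self._overlap_testbed(bias=0.5, seed=21)
        full = self._overlap_testbed(bias=1.0, seed=21)
        assert full.observed > full.expected
        assert full.ratio > 2
        assert null.ratio < half.ratio < full.ratio

    def test_null_bias_gives_unit_overlap_ratio(self):
        test = self._overlap_testbed(bias=0.0, seed=33)
        assert test.ratio == pytest.approx(1.0, abs=0.5)

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            ProteomeScreen([])

    def test_without_tracks_no_cc_statistics(self, small_proteome):
        _, records, _ = small_proteome
        res = ProteomeScreen(records).fit()
        assert res.overlap_tests == {}
        assert "CC+Q4" not in res.cooccurrence


def _write_species_bundle(root, species, spec, plant_seed=0):
    records, truth = generate_proteome(spec)
    fasta = root / f"{species}.fasta"
    write_fasta(records, fasta)
    track_dir = root / f"{species}_tracks"
    track_dir.mkdir()
    tracks, _ = generate_cc_tracks(
        records, truth, CCPlantSpec(p_cc=0.2, overlap_bias=0.5, seed=plant_seed)
    )
    by_id = {r.id: r.seq for r in records}
    for pid, track in tracks.items():
        (track_dir / f"{pid}.track").write_text(write_track(track, by_id[pid]))
    return fasta, track_dir


@pytest.fixture(scope="module")
def six_species_run(tmp_path_factory):
    """Synthetic 6-species bundle with a planted decreasing A4/Q4 trend."""
    root = tmp_path_factory.mktemp("bundle")
    mya = {"sp0": 0, "sp1": 220, "sp2": 440, "sp3": 660, "sp4": 880, "sp5": 1100}
    proteomes, tracks = {}, {}
    for i, (species, m) in enumerate(mya.items()):
        spec = ProteomeSpec(
            n_proteins=250, p_Q4=0.06, p_A4=0.20 - 0.00012 * m,
            p_QA4=0.02, cooccurrence_factor=1.5, seed=100 + i,
        )
        fasta, track_dir = _write_species_bundle(root, species, spec, 200 + i)
        proteomes[species] = str(fasta)
        tracks[species] = str(track_dir)
    config = RunConfig(
        proteomes=proteomes, tracks=tracks, divergence_mya=mya,
        outdir=str(root / "out"), seed=1,
    )
    results = run_screen(config)
    return config, results


class TestRunScreen:
    def test_outputs_written(self, six_species_run):
        config, results = six_species_run
        out = Path(config.outdir)
        assert (out / "species_summary.tsv").exists()
        assert (out / "sp0.runs.tsv").exists()
        assert (out / "sp0.venn.json").exists()
        corr = json.loads((out / "phylo_correlations.json").read_text())
        assert "a4_q4_ratio" in corr

    def test_planted_trend_detected(self, six_species_run):
        config, _ = six_species_run
        corr = json.loads(
            (Path(config.outdir) / "phylo_correlations.json").read_text()
        )
        assert corr["a4_q4_ratio"]["r"] < 0

    def test_rerun_is_deterministic(self, six_species_run, tmp_path):
        config, _ = six_species_run
        config2 = RunConfig(
            proteomes=config.proteomes, tracks=config.tracks,
            divergence_mya=config.divergence_mya, outdir=str(tmp_path / "out2"),
            seed=config.seed,
        )
        run_screen(config2)
        a = (Path(config.outdir) / "species_summary.tsv").read_text()
        b = (Path(config2.outdir) / "species_summary.tsv").read_text()
        assert a == b

    def test_missing_tracks_skips_cc_stages(self, six_species_run, tmp_path):
        config, _ = six_species_run
        sp = next(iter(config.proteomes))
        cfg = RunConfig(
            proteomes={sp: config.proteomes[sp]},
            tracks={sp: str(tmp_path / "nope")},
            outdir=str(tmp_path / "out3"),
        )
        results = run_screen(cfg)
        assert results[sp].overlap_tests == {}

    def test_empty_fasta_clean_error(self, tmp_path):
        bad = tmp_path / "empty.fasta"
        bad.write_text("")
        with pytest.raises(SequenceError, match="empty.fasta"):
            run_screen(RunConfig(proteomes={"x": str(bad)}, outdir=str(tmp_path / "o")))


class TestRunDesign:
    def test_variant_bundle(self, tmp_path):
        base = tmp_path / "base.fasta"
        write_fasta([ProteinRecord("RUNX2-ccd", pep.RUNX2_CCD)], base)
        variants = run_design(
            base, pep.RUNX2_CCD_ANCHORS,
            {"cc_plus": {"n_heptads": 2}, "cc_minus": {"n_sites": 2},
             "polyA_deltas": [12, -6]},
            tmp_path / "design",
        )
        assert len(variants) == 4
        out = read_fasta(tmp_path / "design" / "variants.fasta")
        assert len(out) == 4
        report = json.loads((tmp_path / "design" / "design_report.json").read_text())
        assert "register" in report and "naive_min_pseudo_p" in report

    def test_plus12_rescans_to_29(self, tmp_path):
        from repeatcc.repeats import scan_homopolymer

        base = tmp_path / "base.fasta"
        write_fasta([ProteinRecord("RUNX2-ccd", pep.RUNX2_CCD)], base)
        variants = run_design(
            base, pep.RUNX2_CCD_ANCHORS, {"polyA_deltas": [12]}, tmp_path / "d2"
        )
        assert [r.length for r in scan_homopolymer(variants[0].seq, "A", 4)] == [29]


class TestCLI:
    def test_scan_command(self, tmp_path):
        fasta = tmp_path / "p.fasta"
        write_fasta(
            [ProteinRecord("a", "MQQQQM"), ProteinRecord("b", "MAAAAM")], fasta
        )
        runner = CliRunner()
        result = runner.invoke(cli_main, [
            "scan", str(fasta), "--out", str(tmp_path / "runs.tsv"),
            "--flags-out", str(tmp_path / "flags.tsv"),
        ])
        assert result.exit_code == 0, result.output
        assert (tmp_path / "runs.tsv").read_text().count("\n") == 3  # header + 2

    def test_simulate_then_screen(self, tmp_path):
        runner = CliRunner()
        sim_dir = tmp_path / "syn"
        result = runner.invoke(cli_main, [
            "simulate", "--n-proteins", "60", "--seed", "5",
            "--p-cc", "0.3", "--outdir", str(sim_dir),
        ])
        assert result.exit_code == 0, result.output
        config = {
            "proteomes": {"syn": str(sim_dir / "proteome.fasta")},
            "tracks": {"syn": str(sim_dir / "tracks")},
            "outdir": str(tmp_path / "out"),
        }
        cfg_path = tmp_path / "cfg.yaml"
        cfg_path.write_text(yaml.safe_dump(config))
        result = runner.invoke(cli_main, ["screen", str(cfg_path)])
        assert result.exit_code == 0, result.output
        assert (tmp_path / "out" / "syn.summary.tsv").exists()

    def test_cd_command(self, tmp_path):
        from repeatcc.cd import write_cd_file
        from repeatcc.simulate import generate_cd_fixture

        spectrum, _ = generate_cd_fixture(1.0, 1.10, seed=0)
        path = tmp_path / "cd.tsv"
        write_cd_file(spectrum, path)
        runner = CliRunner()
        result = runner.invoke(cli_main, [
            "cd", str(path), "--out", str(tmp_path / "cd.json"),
        ])
        assert result.exit_code == 0, result.output
        payload = json.loads((tmp_path / "cd.json").read_text())
        assert payload["ratio_222_208"] == pytest.approx(1.10, abs=0.02)
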