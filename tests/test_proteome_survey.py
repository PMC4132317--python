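"""Survey orchestration: cells, tables, reverse search, exclusivity flags."""

import numpy as np
import pytest

from scsurvey.pairwise_align import local_align
from scsurvey.proteome_survey import (
    SurveyConfig,
    SurveyTable,
    flag_exclusives,
    reverse_search,
    survey,
)
from scsurvey.seqio import ProteinRecord
from scsurvey.shuffle_null import SimilarityTier
from scsurvey.synthetic_data import (
    SimConfig,
    make_exclusive_chimera,
    make_cc_protein,
    make_survey_fixture,
    mutate_sequence,
    random_background_sequence,
)


@pytest.fixture(scope="module")
def small_world(scheme):
    rng = np.random.default_rng(42)
    from scsurvey.synthetic_data import background_frequencies

    bg = background_frequencies()
    q = ProteinRecord("query1", random_background_sequence(150, rng, bg))
    proteomes = {
        "tax1": [q]
        + [ProteinRecord(f"t1d{i}", random_background_sequence(150, rng, bg)) for i in range(4)],
        "tax2": [ProteinRecord(f"t2d{i}", random_background_sequence(150, rng, bg)) for i in range(5)],
    }
    return q, proteomes


class TestSurvey:
    def test_self_hit_cell(self, scheme, small_world):
        q, proteomes = small_world
        table = survey([q], proteomes, scheme)
        cell = table.cell("tax1", "query1")
        self_bits = local_align(q, q, scheme).bit_score
        assert cell.best_hit_id == "query1"
        assert cell.max_bits == pytest.approx(self_bits)
        assert cell.tier == SimilarityTier.high

    def test_staged_divergence_monotone(self, scheme):
        # planted orthologs at increasing divergence: max_bits decreases
        rng = np.random.default_rng(7)
        from scsurvey.synthetic_data import background_frequencies

        bg = background_frequencies()
        q = ProteinRecord("q", random_background_sequence(250, rng, bg))
        proteomes = {}
        for name, t in (("near", 0.02), ("mid", 0.4), ("far", 1.5)):
            orth = ProteinRecord(f"{name}_orth", mutate_sequence(q.seq, t, rng, bg=bg))
            decoys = [
                ProteinRecord(f"{name}_d{i}", random_background_sequence(250, rng, bg))
                for i in range(3)
            ]
            proteomes[name] = [orth] + decoys
        table = survey([q], proteomes, scheme)
        bits = [table.cell(n, "q").max_bits for n in ("near", "mid", "far")]
        assert bits[0] > bits[1] > bits[2]

    def test_proteome_order_invariance(self, scheme, small_world):
        q, proteomes = small_world
        t1 = survey([q], proteomes, scheme)
        reordered = {k: list(reversed(v)) for k, v in proteomes.items()}
        t2 = survey([q], reordered, scheme)
        for key, cell in t1.cells.items():
            assert t2.cells[key].best_hit_id == cell.best_hit_id
            assert t2.cells[key].max_bits == cell.max_bits

    def test_best_hit_realignment_reproduces_max(self, scheme, small_world):
        q, proteomes = small_world
        table = survey([q], proteomes, scheme)
        for (taxon, qid), cell in table.cells.items():
            if cell.no_hit:
                continue
            hit = next(r for r in proteomes[taxon] if r.id == cell.best_hit_id)
            res = local_align(q, hit, scheme)
            assert res.bit_score == pytest.approx(cell.max_bits)

    def test_empty_proteome_rejected(self, scheme, small_world):
        q, _ = small_world
        with pytest.raises(ValueError, match="empty"):
            survey([q], {"t": []}, scheme)

    def test_cell_cache_reused(self, scheme, small_world):
        q, proteomes = small_world
        cache = {}
        t1 = survey([q], proteomes, scheme, cache=cache)
        assert len(cache) == 2
        t2 = survey([q], proteomes, scheme, cache=cache)
        for key in t1.cells:
            assert t2.cells[key] is t1.cells[key]


class TestTableSerialization:
    def test_tsv_roundtrip_lossless(self, scheme, small_world, tmp_path):
        q, proteomes = small_world
        cfg = SurveyConfig(null_model=True, seed=5)
        table = survey([q], proteomes, scheme, cfg)
        path = tmp_path / "table.tsv"
        table.to_tsv(path)
        back = SurveyTable.from_tsv(path)
        assert set(back.cells) == set(table.cells)
        for key, cell in table.cells.items():
            b = back.cells[key]
            assert b.max_bits == pytest.approx(round(cell.max_bits, 4))
            assert b.tier == cell.tier
            assert b.best_hit_id == cell.best_hit_id

    def test_markdown_rendering_marks(self, scheme, small_world):
        q, proteomes = small_world
        table = survey([q], proteomes, scheme)
        md = table.render_markdown()
        assert "**" in md  # self hit >= 100 bits is bold
        assert "low similarity" in md  # decoy-only taxon


@pytest.fixture(scope="module")
def world(scheme):
    rng = np.random.default_rng(3)
    from scsurvey.synthetic_data import background_frequencies

    bg = background_frequencies()
    chimera, tail = make_exclusive_chimera(3000, 1.0 / 3.0, seed=8)
    reference = [make_cc_protein(300, k % 7, seed=700 + k) for k in range(4)] + [
        ProteinRecord(f"glob{i}", random_background_sequence(300, rng, bg))
        for i in range(6)
    ]
    return chimera, tail, reference


class TestReverseSearch:

    def test_top_hits_are_c_terminal_restricted(self, scheme, world):
        chimera, tail, reference = world
        hits = reverse_search(chimera, reference, scheme)
        strong = [(c, flag) for c, flag in hits if c.max_bits >= 50]
        assert strong, "no strong hits found"
        assert all(flag for _, flag in strong)

    def test_full_region_matches_survey(self, scheme, world):
        chimera, _, reference = world
        full = reverse_search(chimera, reference, scheme, region=(0, len(chimera.seq)))
        plain = reverse_search(chimera, reference, scheme)
        assert [(c.best_hit_id, c.max_bits) for c, _ in full] == [
            (c.best_hit_id, c.max_bits) for c, _ in plain
        ]
        table = survey([chimera], {"ref": reference}, scheme)
        assert table.cell("ref", chimera.id).max_bits == pytest.approx(plain[0][0].max_bits)

    def test_no_positive_pair_empty(self, scheme):
        subject = ProteinRecord("s", "G" * 100)
        assert reverse_search(subject, [ProteinRecord("p", "P" * 100)], scheme) == []

    def test_empty_proteome_empty(self, scheme, world):
        chimera, _, _ = world
        assert reverse_search(chimera, [], scheme) == []

    def test_region_bounds_checked(self, scheme, world):
        chimera, _, reference = world
        with pytest.raises(ValueError, match="out of bounds"):
            reverse_search(chimera, reference, scheme, region=(0, len(chimera.seq) + 1))


class TestExclusiveFlags:
    def test_fixture_flags_only_chimera_taxon(self, scheme):
        panel, proteomes, truth = make_survey_fixture(SimConfig(seed=3))
        cfg = SurveyConfig(null_model=True, seed=3)
        table = survey(panel, proteomes, scheme, cfg)
        assert flag_exclusives(table) == [("taxon_d", "Q_coiledcoil")]

    def test_without_null_model_warns_and_returns_empty(self, scheme, small_world, caplog):
        q, proteomes = small_world
        table = survey([q], proteomes, scheme)
        import logging

        with caplog.at_level(logging.WARNING, logger="scsurvey.survey"):
            assert flag_exclusives(table) == []
        assert len(caplog.records) == len(table.cells)


class TestSurveyConfigIO:
    def test_yaml_roundtrip(self, tmp_path):
        cfg = SurveyConfig(e_max=50.0, null_model=True, seed=9)
        p = tmp_path / "cfg.yaml"
        cfg.to_yaml(p)
        back = SurveyConfig.from_yaml(p)
        assert back.e_max == 50.0 and back.null_model and back.seed == 9
        assert tuple(back.tier_thresholds) == (50.0, 100.0)
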