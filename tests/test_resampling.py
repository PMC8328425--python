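import numpy as np
import pytest

from oracles import exhaustive_subsample_stats
from trapnest.diversity import fdis, make_reference, ted, top
from trapnest.io import Dataset, NestRecord, SiteRecord, Taxon, UGSType
from trapnest.resampling import (
    ResamplingConfig,
    bootstrap_site,
    eligible_sites,
    summaries_to_frame,
    summarize_all,
)
from trapnest.traits import nest_traits, z_transform


def _make_site(site_id="S1", ugs=UGSType.HOME_GARDEN):
    return SiteRecord(site_id, ugs, open_green=0.3, impervious=0.3, edge_density=0.02)


def _nests(site_id, taxon, count, rng, start=0):
    out = []
    for i in range(count):
        total = int(rng.integers(2, 15))
        par = int(rng.integers(0, total // 2 + 1))
        ne = int(rng.integers(0, total - par + 1))
        out.append(
            NestRecord(f"{site_id}-{taxon.value}{start + i}", site_id, taxon, "sp", total, par, ne)
        )
    return out


class TestEligibility:
    def test_min_tubes_threshold_per_taxon(self, rng):
        sites = [_make_site("A"), _make_site("B")]
        nests = (
            _nests("A", Taxon.BEE, 7, rng)
            + _nests("B", Taxon.BEE, 8, rng)
            + _nests("B", Taxon.WASP, 3, rng)
        )
        data = Dataset(nests=tuple(nests), sites=tuple(sites))
        config = ResamplingConfig()
        assert eligible_sites(data, Taxon.BEE, config) == ["B"]
        assert eligible_sites(data, Taxon.WASP, config) == []

    def test_config_guards(self):
        with pytest.raises(ValueError):
            ResamplingConfig(min_tubes=7, draw_size=7)
        with pytest.raises(ValueError):
            ResamplingConfig(draw_size=3, min_tubes=8)


class TestBootstrapSite:
    def _site_inputs(self, n, rng, identical=False):
        if identical:
            nests = [
                NestRecord(f"n{i}", "S1", Taxon.BEE, "sp", 6, 1, 2) for i in range(n)
            ]
            z = np.zeros((n, 3))
            return nests, z
        nests = _nests("S1", Taxon.BEE, n, rng)
        z = z_transform([nest_traits(x) for x in nests], Taxon.BEE).values
        return nests, z

    def test_average_matches_exhaustive_enumeration(self, rng):
        """With 8 tubes there are only C(8,7)=8 possible draws; the
        bootstrap mean of every statistic must sit within 3 Monte-Carlo
        standard errors of the exhaustive subsample average."""
        nests, z = self._site_inputs(8, rng)
        config = ResamplingConfig(reps=999, seed=21)
        ref = make_reference(7, 3, seed=config.seed)
        summary = bootstrap_site(nests, z, config)
        emerged = np.array([n.emerged_cells for n in nests], dtype=float)
        checks = {
            "top": (z, lambda pts: top(pts)),
            "ted": (z, lambda pts: ted(pts, ref)),
            "fdis": (z, lambda pts: fdis(pts)),
            "offspring_production": (emerged, lambda v: v.mean()),
        }
        for stat_name, (values, stat) in checks.items():
            exact = exhaustive_subsample_stats(values, 7, stat)
            se = exact.std(ddof=0) / np.sqrt(config.reps)
            assert getattr(summary, stat_name) == pytest.approx(
                exact.mean(), abs=max(3 * se, 1e-12)
            ), stat_name

    def test_identical_tubes_degenerate_cloud(self):
        nests, z = self._site_inputs(10, None, identical=True)
        summary = bootstrap_site(nests, z, ResamplingConfig(seed=3))
        assert summary.top == 0.0
        assert summary.fdis == 0.0

    def test_same_seed_bit_identical(self, rng):
        nests, z = self._site_inputs(9, rng)
        config = ResamplingConfig(reps=99, seed=5)
        assert bootstrap_site(nests, z, config) == bootstrap_site(nests, z, config)

    def test_too_few_tubes_rejected(self, rng):
        nests, z = self._site_inputs(7, rng)
        with pytest.raises(ValueError, match="at least 8"):
            bootstrap_site(nests, z, ResamplingConfig())

    def test_all_tubes_mean_mode(self, rng):
        nests, z = self._site_inputs(9, rng)
        config = ResamplingConfig(reps=49, seed=5, mean_traits="all_tubes")
        summary = bootstrap_site(nests, z, config)
        assert summary.offspring_production == pytest.approx(
            np.mean([n.emerged_cells for n in nests])
        )


class TestSummarizeAll:
    def _dataset(self, rng):
        sites = [_make_site("A"), _make_site("B"), _make_site("C")]
        nests = (
            _nests("A", Taxon.BEE, 10, rng)
            + _nests("B", Taxon.BEE, 9, rng)
            + _nests("B", Taxon.WASP, 12, rng)
            + _nests("C", Taxon.WASP, 5, rng)
        )
        return Dataset(nests=tuple(nests), sites=tuple(sites))

    def test_one_row_per_eligible_site_taxon(self, rng):
        data = self._dataset(rng)
        rows = summarize_all(data, ResamplingConfig(reps=29, seed=1))
        assert {(r.site_id, r.taxon) for r in rows} == {("A", "bee"), ("B", "bee"), ("B", "wasp")}

    def test_site_order_invariance(self, rng):
        """Per-site substreams make results independent of table order."""
        data = self._dataset(rng)
        flipped = Dataset(nests=tuple(reversed(data.nests)), sites=tuple(reversed(data.sites)))
        config = ResamplingConfig(reps=49, seed=9)
        a = {(r.site_id, r.taxon): r for r in summarize_all(data, config)}
        b = {(r.site_id, r.taxon): r for r in summarize_all(flipped, config)}
        assert a == b

    def test_ineligible_sites_do_not_perturb(self, rng):
        data = self._dataset(rng)
        pruned = Dataset(
            nests=tuple(n for n in data.nests if n.site_id != "C"),
            sites=data.sites,
        )
        config = ResamplingConfig(reps=49, seed=9)
        full = {(r.site_id, r.taxon): r for r in summarize_all(data, config)}
        part = {(r.site_id, r.taxon): r for r in summarize_all(pruned, config)}
        assert part == full

    def test_bootstrap_mean_tracks_generator_expectation(self, survey_dataset):
        """Across many sites the bootstrap-averaged mean brood size must
        agree with the generator's configured mean (6.68 bees / 4.16
        wasps) within Monte-Carlo error."""
        config = ResamplingConfig(reps=49, seed=2)
        df = summaries_to_frame(summarize_all(survey_dataset, config))
        bee = df[df.taxon == "bee"]["mean_total_cells"]
        wasp = df[df.taxon == "wasp"]["mean_total_cells"]
        assert bee.mean() == pytest.approx(6.68, abs=4 * bee.std() / np.sqrt(len(bee)) + 0.05)
        assert wasp.mean() == pytest.approx(4.16, abs=4 * wasp.std() / np.sqrt(len(wasp)) + 0.05)
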