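"""Primer-site search, in-silico PCR and panel assembly."""

import numpy as np
import pytest

from ampliconid import (
    DEFAULT_PRIMER_PAIRS,
    PrimerPair,
    ReferencePanel,
    build_panel,
    discriminability_report,
    find_primer_sites,
    in_silico_pcr,
    reverse_complement,
    synthetic_references,
)
from ampliconid.primers import IUPAC_SETS, iupac_hamming
from ampliconid.refpanel import NoAmpliconError

from oracle_dp import oracle_p_distance

P12S = DEFAULT_PRIMER_PAIRS[0]  # 22 / 20 bp primers


def _random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


def _template(filler):
    """Forward primer + filler + reverse-complemented reverse primer."""
    return P12S.forward + filler + reverse_complement(P12S.reverse)


class TestFindPrimerSites:
    def test_exact_sites_on_constructed_template(self, rng):
        tmpl = _template(_random_dna(rng, 100))
        fwd = find_primer_sites(tmpl, P12S.forward, "forward", 0, P12S.name)
        rev = find_primer_sites(tmpl, P12S.reverse, "reverse", 0, P12S.name)
        assert [(m.start, m.end, m.mismatches) for m in fwd] == [(0, 22, 0)]
        assert [(m.start, m.end, m.mismatches) for m in rev] == [(122, 142, 0)]

    def test_substitution_in_site_counts_one_mismatch(self, rng):
        tmpl = _template(_random_dna(rng, 100))
        mutated = ("G" if tmpl[5] != "G" else "C") + tmpl[6:]
        mutated = tmpl[:5] + mutated
        hits = find_primer_sites(mutated, P12S.forward, "forward", 2, P12S.name)
        top = hits[0]
        assert (top.start, top.end, top.mismatches) == (0, 22, 1)

    def test_agrees_with_bruteforce_window_scan(self, rng):
        template = _random_dna(rng, 300)
        probe = template[137:157]  # guaranteed 0-mismatch site
        hits = find_primer_sites(template, probe, "forward", 3)
        # independent oracle: score every window by explicit Hamming count
        expected = []
        for s in range(len(template) - len(probe) + 1):
            mm = sum(
                1
                for a, b in zip(template[s : s + len(probe)], probe)
                if IUPAC_SETS[a].isdisjoint(IUPAC_SETS[b])
            )
            if mm <= 3:
                expected.append((mm, s))
        assert [(h.mismatches, h.start) for h in hits] == sorted(expected)

    def test_iupac_code_matches_compatible_base(self):
        # R = A or G: a primer R over a template A is not a mismatch
        hits = find_primer_sites("AACCGGTT", "ARCCGGTT", "forward", 0)
        assert hits and hits[0].mismatches == 0

    def test_non_dna_reference_rejected_with_position(self):
        with pytest.raises(ValueError, match="position 3"):
            find_primer_sites("ACGXACGT", "ACGT", "forward", 0)


class TestInSilicoPcr:
    def test_constructed_template(self, rng):
        filler = _random_dna(rng, 100)
        region = in_silico_pcr(_template(filler), P12S, max_mismatch=0)
        assert region.target_seq == filler
        assert (region.target_start, region.target_end) == (22, 122)
        assert region.full_len == 142

    def test_found_on_reverse_complemented_reference(self, rng):
        filler = _random_dna(rng, 100)
        region = in_silico_pcr(reverse_complement(_template(filler)), P12S, max_mismatch=0)
        assert region.target_seq == filler
        assert region.full_len == 142

    def test_nearest_reverse_site_within_max_product_wins(self, rng):
        rc_rev = reverse_complement(P12S.reverse)
        t_short = _random_dna(rng, 80 - P12S.primer_len_sum)
        mid = _random_dna(rng, 300 - 80 - len(rc_rev))
        tmpl = P12S.forward + t_short + rc_rev + mid + rc_rev
        region = in_silico_pcr(tmpl, P12S, max_mismatch=0, max_product=250)
        # exhaustive enumeration of (forward, reverse) site pairs
        fwd = find_primer_sites(tmpl, P12S.forward, "forward", 0)
        rev = find_primer_sites(tmpl, P12S.reverse, "reverse", 0)
        products = sorted(
            r.end - f.start for f in fwd for r in rev if r.start >= f.end and r.end - f.start <= 250
        )
        assert region.full_len == products[0] == 80

    def test_no_amplicon_raises(self, rng):
        with pytest.raises(NoAmpliconError, match=P12S.name):
            in_silico_pcr(_random_dna(rng, 200), P12S, max_mismatch=0)

    def test_coordinates_reproduce_target(self, rng):
        tmpl = _template(_random_dna(rng, 100))
        region = in_silico_pcr(tmpl, P12S, max_mismatch=0)
        assert tmpl[region.target_start : region.target_end] == region.target_seq


class TestBuildPanel:
    def test_three_species_three_pairs(self):
        refs = synthetic_references(species=("s1", "s2", "s3"), seed=2)
        panel = build_panel(refs)
        assert len(panel) == 9
        assert sorted(panel.species) == ["s1", "s2", "s3"]

    def test_missing_site_logged_not_fatal(self, caplog):
        refs = dict(synthetic_references(species=("s1", "s2", "s3"), seed=2))
        ki = DEFAULT_PRIMER_PAIRS[2]
        src, seq = refs["s3"]
        # destroy the 16S_Ki forward site on both strands
        broken = seq.replace(ki.forward, "A" * len(ki.forward)).replace(
            reverse_complement(ki.forward), "T" * len(ki.forward)
        )
        refs["s3"] = (src, broken)
        with caplog.at_level("WARNING"):
            panel = build_panel(refs)
        assert len(panel) == 8
        assert ("s3", "16S_Ki") not in panel
        assert any("s3/16S_Ki" in rec.message for rec in caplog.records)

    def test_fasta_round_trip_identity(self, tmp_path, panel3):
        path = tmp_path / "panel.fa"
        panel3.to_fasta(path)
        reloaded = ReferencePanel.from_fasta(path)
        assert set(reloaded.regions) == set(panel3.regions)
        for key in panel3.regions:
            a, b = panel3[key], reloaded[key]
            assert (a.target_seq, a.target_start, a.target_end, a.full_len) == (
                b.target_seq, b.target_start, b.target_end, b.full_len
            )

    def test_full_len_decomposes_into_target_plus_primers(self, panel13):
        by_name = {p.name: p for p in DEFAULT_PRIMER_PAIRS}
        for region in panel13:
            pair = by_name[region.primer_pair]
            assert region.full_len == len(region.target_seq) + pair.primer_len_sum
            lo, hi = pair.expected_len_range
            assert lo <= region.full_len <= hi


class TestDiscriminability:
    @staticmethod
    def _panel_from_targets(targets):
        panel = ReferencePanel()
        from ampliconid.refpanel import AmpliconRegion

        for i, t in enumerate(targets):
            panel.add(
                AmpliconRegion(
                    species=f"sp{i}", primer_pair="P", target_seq=t,
                    source_id=f"src{i}", target_start=0, target_end=len(t),
                    full_len=len(t),
                )
            )
        return panel

    def test_identical_sequences_distance_zero(self):
        panel = self._panel_from_targets(["ACGTACGT", "ACGTACGT"])
        df, min_d = discriminability_report(panel, "P")
        assert min_d == 0.0

    def test_single_substitution_quarter(self):
        panel = self._panel_from_targets(["ACGT", "ACGA"])
        df, min_d = discriminability_report(panel, "P")
        assert df.loc["sp0", "sp1"] == pytest.approx(0.25)

    def test_matrix_matches_independent_dp_oracle(self, rng):
        targets = ["".join(rng.choice(list("ACGT"), 60)) for _ in range(4)]
        panel = self._panel_from_targets(targets)
        df, _ = discriminability_report(panel, "P")
        for i in range(4):
            for j in range(i + 1, 4):
                assert df.iloc[i, j] == pytest.approx(
                    oracle_p_distance(targets[i], targets[j]), abs=1e-12
                )

    def test_symmetric_zero_diagonal_positive_min(self, panel13):
        df, min_d = discriminability_report(panel13, "16S_KH")
        assert np.allclose(df.values, df.values.T)
        assert np.all(np.diag(df.values) == 0)
        assert min_d > 0

    def test_single_species_errors(self):
        panel = self._panel_from_targets(["ACGT"])
        with pytest.raises(ValueError):
            discriminability_report(panel, "P")
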