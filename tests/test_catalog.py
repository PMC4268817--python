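"""Event catalog: parsing, filters, replicate intersection, catalog merge,
classification, controls, expression filter."""
import numpy as np
import pandas as pd
import pytest

from ejcsplice import catalog as cat
from ejcsplice.annotation import Exon, Gene, GenomeAnnotation, Transcript
from ejcsplice.catalog import (CassetteEvent, CatalogError, ExpressionRecord,
                               IntronEvent, MisoThresholds, build_controls,
                               classify_events, classify_intron_events,
                               combine_contrasts, expression_filter,
                               filter_miso_events, intersect_replicates,
                               merge_catalogs, parse_event_table,
                               write_event_table)


def _miso_row(event_id="e1", contrast="eIF4A3", psi1=0.8, psi2=0.5, bf=8.0,
              inc=30, skip=30, ca=(500, 600), up=(100, 200), dn=(900, 1000),
              chrom="chr1", strand="+"):
    return dict(event_id=event_id, event_type="SE", chrom=chrom, strand=strand,
                up_start=up[0], up_end=up[1], ca_start=ca[0], ca_end=ca[1],
                dn_start=dn[0], dn_end=dn[1], contrast=contrast,
                psi1=psi1, psi2=psi2, diff=psi1 - psi2, bayes_factor=bf,
                inc_reads=inc, skip_reads=skip)


def _write(tmp_path, rows, name="t.tsv", columns=cat.MISO_COLUMNS):
    p = tmp_path / name
    pd.DataFrame(rows, columns=columns).to_csv(p, sep="\t", index=False)
    return p


def _event(**kw):
    base = dict(event_id="e1", chrom="chr1", strand="+",
                up_start=100, up_end=200, ca_start=500, ca_end=600,
                dn_start=900, dn_end=1000)
    base.update(kw)
    return CassetteEvent(**base)


class TestParse:
    def test_empty_table_gives_empty_list(self, tmp_path):
        p = _write(tmp_path, [])
        assert parse_event_table(p, "miso") == []

    def test_psi_out_of_range_names_the_line(self, tmp_path):
        p = _write(tmp_path, [_miso_row(), _miso_row(event_id="e2", psi1=1.2,
                                                    psi2=0.2)])
        with pytest.raises(CatalogError, match="line 2"):
            parse_event_table(p, "miso")

    def test_unknown_dialect_is_an_error(self, tmp_path):
        p = _write(tmp_path, [_miso_row()])
        with pytest.raises(CatalogError, match="dialect"):
            parse_event_table(p, "nonsense")

    def test_round_trip_preserves_event_set(self, tmp_path, small_events):
        src = tmp_path / "src.tsv"
        small_events.miso[("eIF4A3", 1)].to_csv(src, sep="\t", index=False)
        first = parse_event_table(src, "miso")
        out = tmp_path / "round.tsv"
        write_event_table(first, out)
        second = parse_event_table(out, "miso")
        assert first == second
        assert len(first) > 0

    def test_intron_retention_rows_parse_with_abutting_flanks(self, tmp_path):
        row = _miso_row()
        row.update(event_type="RI", up_start=100, up_end=500, ca_start=500,
                   ca_end=900, dn_start=900, dn_end=1000)
        (ev,) = parse_event_table(_write(tmp_path, [row]), "miso")
        assert isinstance(ev, IntronEvent)
        assert ev.intron_start == 500 and ev.intron_end == 900

    def test_non_abutting_intron_flanks_rejected(self):
        with pytest.raises(CatalogError, match="abut"):
            IntronEvent("x", "chr1", "+", 500, 900, 100, 450, 900, 1000)


class TestFilter:
    CASES = [
        # (diff, bf, inc, skip, expected_kept)
        (0.30, 8.0, 30, 30, True),
        (0.10, 8.0, 30, 30, False),    # |dPsi| boundary, strict
        (0.101, 8.0, 30, 30, True),
        (0.30, 5.0, 30, 30, False),    # evidence boundary, strict
        (0.30, 5.01, 30, 30, True),
        (0.30, 8.0, 10, 30, False),    # inclusion reads boundary
        (0.30, 8.0, 11, 30, True),
        (0.30, 8.0, 30, 10, False),    # skipping reads boundary
        (-0.30, 8.0, 30, 30, True),    # direction-agnostic magnitude
        (0.30, 8.0, 11, 9, False),     # total boundary: 20 not > 20
        (0.05, 20.0, 100, 100, False),
        (0.0, 0.0, 0, 0, False),
    ]

    def test_filter_matches_row_by_row_predicate(self):
        events = []
        for i, (d, bf, inc, skip, _) in enumerate(self.CASES):
            events.append(CassetteEvent(
                event_id=f"e{i}", chrom="chr1", strand="+",
                up_start=100, up_end=200,
                ca_start=500 + 1000 * i, ca_end=600 + 1000 * i,
                dn_start=900, dn_end=1000,
                psi_control={"eIF4A3": min(1.0, 0.5 + d / 2)},
                psi_kd={"eIF4A3": max(0.0, 0.5 - d / 2)},
                delta_psi={"eIF4A3": d}, evidence={"eIF4A3": bf},
                inc_reads={"eIF4A3": inc}, skip_reads={"eIF4A3": skip}))
        kept = {e.event_id for e in filter_miso_events(events, MisoThresholds())}
        # independent row-by-row predicate
        expected = {f"e{i}" for i, (d, bf, inc, skip, _) in enumerate(self.CASES)
                    if abs(d) > 0.1 and bf > 5 and inc > 10 and skip > 10
                    and inc + skip > 20}
        assert kept == expected
        assert expected == {f"e{i}" for i, c in enumerate(self.CASES) if c[4]}

    def test_missing_counts_is_an_error(self):
        ev = _event(delta_psi={"eIF4A3": 0.5}, evidence={"eIF4A3": 9.0})
        with pytest.raises(CatalogError, match="counts"):
            filter_miso_events([ev])


def _sig_event(eid, ca, diff, contrast="eIF4A3", strand="+", chrom="chr1",
               up=(100, 200), dn=(900, 1000), bf=9.0):
    return CassetteEvent(
        event_id=eid, chrom=chrom, strand=strand,
        up_start=up[0], up_end=up[1], ca_start=ca[0], ca_end=ca[1],
        dn_start=dn[0], dn_end=dn[1],
        psi_control={contrast: min(1.0, 0.5 + diff)}, psi_kd={contrast: 0.5},
        delta_psi={contrast: diff}, evidence={contrast: bf},
        inc_reads={contrast: 40}, skip_reads={contrast: 40},
        significant_in=frozenset({contrast}))


class TestIntersectAndMerge:
    def test_disjoint_replicates_give_empty(self):
        a = [_sig_event("a", (500, 600), 0.3)]
        b = [_sig_event("b", (1500, 1600), 0.3)]
        assert intersect_replicates(a, b) == []

    def test_opposite_signs_excluded(self):
        a = [_sig_event("a", (500, 600), 0.3)]
        b = [_sig_event("a", (500, 600), -0.3)]
        assert intersect_replicates(a, b) == []

    def test_delta_is_replicate_mean(self):
        a = [_sig_event("a", (500, 600), 0.3)]
        b = [_sig_event("a", (500, 600), 0.2)]
        (ev,) = intersect_replicates(a, b)
        assert ev.delta_psi["eIF4A3"] == pytest.approx(0.25)

    def test_intersection_equals_keyed_set_oracle(self):
        rng = np.random.default_rng(0)
        def mk(n, seed_offset):
            out = []
            for i in range(n):
                ca = (1000 * int(rng.integers(1, 30)), 1000 * int(rng.integers(1, 30)) + 100)
                out.append(_sig_event(f"x{i}", ca, float(rng.choice([-0.3, 0.3]))))
            return out
        a, b = mk(25, 0), mk(25, 1)
        got = {e.key for e in intersect_replicates(a, b)}
        keyed = {(e.key, np.sign(e.delta_psi["eIF4A3"])) for e in a} & \
                {(e.key, np.sign(e.delta_psi["eIF4A3"])) for e in b}
        assert got == {k for k, _ in keyed}

    def test_merge_with_empty_diffsplice_is_identity(self):
        a = [_sig_event("a", (500, 600), 0.3)]
        merged, audit = merge_catalogs(a, [])
        assert [e.key for e in merged] == [a[0].key] and audit == []

    def test_merge_marks_shared_events_as_both(self):
        miso = [_sig_event("a", (500, 600), 0.3), _sig_event("b", (1500, 1600), 0.3)]
        ds = [_sig_event("a2", (500, 600), 0.25), _sig_event("c", (2500, 2600), 0.3)]
        for e in ds:
            e.source = "DiffSplice"
        merged, audit = merge_catalogs(miso, ds)
        by_key = {e.key: e for e in merged}
        assert len(merged) == 3 and not audit
        shared = by_key[("chr1", "+", 500, 600)]
        assert shared.source == "both"
        # dPsi precedence to the exon-centric caller
        assert shared.delta_psi["eIF4A3"] == pytest.approx(0.3)

    def test_discordant_signs_audited_and_excluded(self):
        miso = [_sig_event("a", (500, 600), 0.3)]
        ds = [_sig_event("a2", (500, 600), -0.3)]
        ds[0].source = "DiffSplice"
        merged, audit = merge_catalogs(miso, ds)
        assert merged == [] and audit[0][1].startswith("discordant")

    def test_merge_size_bounded_and_commutative_up_to_source(self):
        rng = np.random.default_rng(1)
        def mk(n):
            return [_sig_event(f"m{i}", (1000 * int(rng.integers(1, 20)),
                                         1000 * int(rng.integers(1, 20)) + 100), 0.3)
                    for i in range(n)]
        a, b = mk(15), mk(15)
        m1, _ = merge_catalogs(a, b)
        m2, _ = merge_catalogs(b, a)
        assert len(m1) <= len(a) + len(b)
        assert {e.key for e in m1} == {e.key for e in m2}


def _toy_annotation():
    # + strand gene: e0 con, e1 alt, e2 con, e3 alt, e4 con
    exons = [Exon(100, 200), Exon(500, 600, True), Exon(900, 1000),
             Exon(1300, 1400, True), Exon(1700, 1800)]
    gp = Gene("gp", "chr1", "+", exons,
              [Transcript("gp.t1", (0, 1, 2, 3, 4))])
    # gene of 5 constitutive exons for the CtrCON triplet rule
    gc = Gene("gc", "chr1", "+",
              [Exon(5000 + 400 * i, 5100 + 400 * i) for i in range(5)],
              [Transcript("gc.t1", tuple(range(5)))])
    return GenomeAnnotation([gp, gc])


class TestClassify:
    def test_direction_and_alt_class(self):
        ann = _toy_annotation()
        ev = _sig_event("a", (500, 600), 0.25)
        cats, audit = classify_events([ev], ann)
        assert cats[0].direction == "+" and cats[0].annot_class == "ALT"
        assert audit == []

    def test_exact_threshold_gives_direction_none(self):
        ann = _toy_annotation()
        ev = _sig_event("a", (500, 600), 0.1)
        cats, _ = classify_events([ev], ann)
        assert cats[0].direction == "none"

    def test_negative_delta_is_inclusion_up(self):
        ann = _toy_annotation()
        ev = _sig_event("a", (500, 600), -0.25)
        cats, _ = classify_events([ev], ann)
        assert cats[0].direction == "-"

    def test_upf1_only_change_gives_no_ejc_direction(self):
        ann = _toy_annotation()
        ev = _sig_event("a", (500, 600), 0.4, contrast="Upf1")
        cats, _ = classify_events([ev], ann)
        assert cats[0].direction == "none"

    def test_constitutive_cassette_is_con(self):
        ann = _toy_annotation()
        ev = _sig_event("a", (5400, 5500), 0.3, up=(5000, 5100), dn=(5800, 5900))
        cats, _ = classify_events([ev], ann)
        assert cats[0].annot_class == "CON"

    def test_unknown_coordinates_audited(self):
        ann = _toy_annotation()
        ev = _sig_event("a", (123, 456), 0.3)
        cats, audit = classify_events([ev], ann)
        assert cats == [] and "absent" in audit[0][1]

    def test_alternative_flank_excluded_as_complex(self):
        ann = _toy_annotation()
        # cassette = e2 (constitutive) flanked by alt e1 and alt e3
        ev = _sig_event("a", (900, 1000), 0.3, up=(500, 600), dn=(1300, 1400))
        cats, audit = classify_events([ev], ann)
        assert cats == [] and "constitutive" in audit[0][1]

    def test_category_counts_match_enumeration(self):
        """20 events with known flags: per-category counts equal exhaustive
        enumeration over the inputs."""
        rng = np.random.default_rng(2)
        genes, events, expected = [], [], {"+A": 0, "-A": 0, "+C": 0, "-C": 0}
        for i in range(20):
            base = 10_000 * (i + 1)
            alt = bool(rng.integers(2))
            d = float(rng.choice([-0.3, 0.3]))
            exons = [Exon(base, base + 100), Exon(base + 400, base + 500, alt),
                     Exon(base + 800, base + 900)]
            genes.append(Gene(f"g{i}", "chr2", "+", exons,
                              [Transcript(f"g{i}.t1", (0, 1, 2))]))
            events.append(_sig_event(f"e{i}", (base + 400, base + 500), d,
                                     chrom="chr2", up=(base, base + 100),
                                     dn=(base + 800, base + 900)))
            expected[("+" if d > 0.1 else "-") + ("A" if alt else "C")] += 1
        cats, audit = classify_events(events, GenomeAnnotation(genes))
        assert audit == []
        got = {"+A": 0, "-A": 0, "+C": 0, "-C": 0}
        for e in cats:
            got[e.direction + e.annot_class[0]] += 1
        assert got == expected

    def test_intron_event_direction(self):
        ev = IntronEvent("i1", "chr1", "+", 500, 900, 100, 500, 900, 1000,
                         delta_psi={"eIF4A3": -0.3})
        (out,) = classify_intron_events([ev])
        assert out.category == "-"  # increased retention in KD


class TestControls:
    def _pool_event(self, i, diff, psi=0.5, contrast="eIF4A3"):
        return CassetteEvent(
            event_id=f"p{i}", chrom="chr1", strand="+",
            up_start=100, up_end=200, ca_start=500, ca_end=600,
            dn_start=900, dn_end=1000,
            psi_control={contrast: psi}, psi_kd={contrast: psi - diff},
            delta_psi={contrast: diff}, evidence={contrast: 1.0},
            inc_reads={contrast: 40}, skip_reads={contrast: 40})

    @pytest.mark.parametrize("diff,psi,eligible", [
        (0.02, 0.5, True),    # |dPsi| < 0.03, Psi well inside (0.1, 0.9)
        (0.05, 0.5, False),   # splicing change too large
        (0.02, 0.95, False),  # Psi outside the open interval
        (0.02, 0.9, False),   # boundary of the open interval excluded
    ])
    def test_ctr_eligibility_boundaries(self, diff, psi, eligible):
        ann = _toy_annotation()
        with pytest.warns(UserWarning):
            ctr, _ = build_controls([self._pool_event(1, diff, psi=psi)],
                                    ann, {"gp", "gc"}, 10, 0, seed=0)
        assert (len(ctr) == 1) == eligible

    def test_five_constitutive_exons_give_single_middle_triplet(self):
        ann = _toy_annotation()
        with pytest.warns(UserWarning):
            _, con = build_controls([], ann, {"gp", "gc"}, 0, 10, seed=0)
        assert len(con) == 1
        trio = con[0]
        assert (trio.up_start, trio.ca_start, trio.dn_start) == (5400, 5800, 6200)

    def test_unexpressed_genes_excluded(self):
        ann = _toy_annotation()
        with pytest.warns(UserWarning):
            _, con = build_controls([], ann, set(), 0, 10, seed=0)
        assert con == []

    def test_seeded_sampling_is_reproducible(self):
        ann = _toy_annotation()
        pools = [[self._pool_event(i, 0.01) for i in range(5)]] * 2
        with pytest.warns(UserWarning):
            a, _ = build_controls(pools[0], ann, {"gp"}, 3, 0, seed=9)
            b, _ = build_controls(pools[1], ann, {"gp"}, 3, 0, seed=9)
        assert [e.event_id for e in a] == [e.event_id for e in b]


class TestExpressionFilter:
    def test_zero_reads_filtered_out(self):
        recs = [ExpressionRecord("g", "control", 0, 1000),
                ExpressionRecord("g", "eIF4A3", 0, 1000)]
        assert expression_filter(recs) == set()

    def test_worked_arithmetic_retained_at_inclusive_threshold(self):
        # 51 * 200 / 1020 = 10.0 exactly
        recs = [ExpressionRecord("g", "control", 200, 1020, read_length=51),
                ExpressionRecord("g", "eIF4A3", 200, 1020, read_length=51)]
        assert recs[0].coverage == 10.0
        assert expression_filter(recs, threshold=10.0) == {"g"}

    def test_default_read_length_is_51(self):
        assert ExpressionRecord("g", "control", 200, 1020).coverage == 10.0

    def test_needs_control_and_one_kd(self):
        recs = [ExpressionRecord("g", "control", 1000, 1000),
                ExpressionRecord("g", "eIF4A3", 1, 1000)]
        assert expression_filter(recs) == set()

    def test_zero_length_is_an_error(self):
        with pytest.raises(CatalogError):
            ExpressionRecord("g", "control", 10, 0)


class TestCombine:
    def test_combine_contrasts_unions_significance(self):
        a = _sig_event("a", (500, 600), 0.3, contrast="eIF4A3")
        b = _sig_event("a", (500, 600), 0.2, contrast="Y14")
        (ev,) = combine_contrasts([a, b])
        assert ev.significant_in == frozenset({"eIF4A3", "Y14"})
        assert ev.delta_psi == {"eIF4A3": 0.3, "Y14": 0.2}
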