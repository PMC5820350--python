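"""Broken-read breakpoint detection and IS terminus assignment."""

import edlib
import numpy as np
import pytest

from escapewatch import synth
from escapewatch.isscan.breakpoints import (
    BreakpointCluster,
    assign_termini,
    detect_breakpoints,
)
from escapewatch.isscan.align import ReadSet
from escapewatch.isscan.references import ISCatalog, ISElement, revcomp


def planted_events(spectrum):
    return {f"{m.event.subgroup}@{m.event.position}": m.event
            for m in spectrum.modes if m.event is not None}


class TestDetectBreakpoints:
    def test_planted_insertions_recovered(self, scanned, spectrum):
        """Every planted insertion above the support floor is detected with
        the correct position, subgroup, orientation and TSD length."""
        _, events, _ = scanned
        planted = planted_events(spectrum)
        found = {f"{e.subgroup}@{e.position}": e for e in events}
        for label in ("IS10@1200", "IS186@2500", "IS5@900"):
            assert label in found, f"missing {label}"
            assert found[label].tsd_length == planted[label].tsd_length
            assert found[label].orientation == planted[label].orientation

    def test_crossed_over_gap_equals_tsd(self, readset, reference, catalog, spectrum):
        """The left/right breakpoint clusters of an insertion are crossed
        over: the right breakpoint precedes the left by the TSD length."""
        reads, _ = readset
        clusters = detect_breakpoints(reads, reference, min_support=3)
        ev = next(m.event for m in spectrum.modes if m.label == "IS10@1200")
        lefts = [c for c in clusters if c.side == "right_clip" and abs(c.coord - 1200) <= 1]
        rights = [
            c for c in clusters
            if c.side == "left_clip" and abs(c.coord - (1200 - ev.tsd_length + 1)) <= 1
        ]
        assert lefts and rights

    def test_tail_consensus_matches_planted_terminus(
        self, readset, reference, catalog, spectrum
    ):
        reads, _ = readset
        clusters = detect_breakpoints(reads, reference, min_support=3)
        best = max(
            (c for c in clusters if c.side == "right_clip" and abs(c.coord - 1200) <= 3),
            key=lambda c: c.support,
        )
        terminus = catalog["IS10"].seq[: len(best.consensus)]
        dist = edlib.align(best.consensus, terminus, mode="NW")["editDistance"]
        assert dist / len(best.consensus) <= 0.05

    def test_intact_reads_produce_no_supported_clusters(
        self, reference, catalog, spectrum
    ):
        reads, _ = synth.simulate_reads(
            reference, {"intact": 1.0}, catalog, spectrum, depth=400, seed=21
        )
        clusters = detect_breakpoints(reads, reference, min_support=3)
        assert clusters == []

    def test_min_clip_floor_enforced(self, readset, reference):
        reads, _ = readset
        with pytest.raises(ValueError):
            detect_breakpoints(reads, reference, min_clip=10)

    def test_reference_shorter_than_reads_rejected(self, readset):
        from escapewatch.isscan.references import PlasmidReference

        reads, _ = readset
        tiny = PlasmidReference(name="tiny", seq="ACGT" * 10)
        with pytest.raises(ValueError):
            detect_breakpoints(reads, tiny)

    def test_empty_read_set(self, reference):
        assert detect_breakpoints(ReadSet([], []), reference) == []


def make_cluster(side, coord, tail, support=10):
    return BreakpointCluster(
        side=side, coord=coord, support=support, tails=(tail,) * support, consensus=tail
    )


class TestAssignTermini:
    def test_hand_built_pair_within_signature(self, catalog):
        el = catalog["IS10"]
        clusters = [
            make_cluster("right_clip", 1200, el.left_terminus),
            make_cluster("left_clip", 1192, el.right_terminus),
        ]
        events, unassigned = assign_termini(clusters, catalog)
        assert len(events) == 1 and not unassigned
        ev = events[0]
        assert (ev.position, ev.subgroup, ev.orientation, ev.tsd_length) == (1200, "IS10", "+", 9)

    def test_reverse_orientation_detected(self, catalog):
        el = catalog["IS186"]
        rc = revcomp(el.seq)
        clusters = [
            make_cluster("right_clip", 2500, rc[:40]),
            make_cluster("left_clip", 2496, rc[-40:]),
        ]
        events, _ = assign_termini(clusters, catalog)
        assert len(events) == 1
        assert events[0].orientation == "-" and events[0].tsd_length == 5

    def test_gap_outside_signature_left_unassigned(self, catalog):
        el = catalog["IS10"]
        clusters = [
            make_cluster("right_clip", 1200, el.left_terminus),
            make_cluster("left_clip", 1181, el.right_terminus),  # gap 20
        ]
        events, unassigned = assign_termini(clusters, catalog)
        assert events == [] and len(unassigned) == 2

    def test_foreign_tail_left_unassigned(self, catalog):
        rng = np.random.default_rng(0)
        tail = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 40)])
        clusters = [make_cluster("right_clip", 1200, tail)]
        events, unassigned = assign_termini(clusters, catalog)
        assert events == [] and len(unassigned) == 1

    def test_ambiguous_tail_between_subgroups_excluded(self):
        seq = "".join(
            np.array(list("ACGT"))[np.random.default_rng(3).integers(0, 4, 900)]
        )
        twins = ISCatalog(
            [ISElement(name="ISa", seq=seq), ISElement(name="ISb", seq=seq)], merge_rules={}
        )
        clusters = [
            make_cluster("right_clip", 500, seq[:40]),
            make_cluster("left_clip", 495, seq[-40:]),
        ]
        events, unassigned = assign_termini(clusters, twins)
        assert events == []

    def test_microhomology_offset_corrected(self, catalog):
        """If the element start also matches the reference, read clips shift
        but the reported position is corrected back via the tail offset."""
        el = catalog["IS10"]
        # tails that begin 2 bases inside the element: boundary absorbed 2 bp
        clusters = [
            make_cluster("right_clip", 1202, el.seq[2:46]),
            make_cluster("left_clip", 1192, el.right_terminus),
        ]
        events, _ = assign_termini(clusters, catalog)
        assert len(events) == 1 and events[0].position == 1200


class TestOrientationSymmetry:
    def test_mate_strand_labels_do_not_matter(self, reference, catalog, spectrum):
        """Reverse-complementing every read (swapping strand labels) leaves
        detected positions and TSDs unchanged."""
        truth = {"intact": 0.8, "IS10@1200": 0.2}
        reads, _ = synth.simulate_reads(
            reference, truth, catalog, spectrum, depth=400, seed=13
        )
        flipped = ReadSet(list(reads.names), [revcomp(s) for s in reads.seqs])
        ev_a, _ = assign_termini(
            detect_breakpoints(reads, reference, min_support=3), catalog,
            ref_length=len(reference),
        )
        ev_b, _ = assign_termini(
            detect_breakpoints(flipped, reference, min_support=3), catalog,
            ref_length=len(reference),
        )
        key = lambda evs: sorted((e.position, e.subgroup, e.tsd_length) for e in evs)
        assert key(ev_a) == key(ev_b)
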