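import itertools

import numpy as np
import pytest

from cladescreen.errors import ConfigError, ContractError, ValidationError
from cladescreen.screen import (
    CandidateMarker,
    Rejection,
    ScreenConfig,
    assign_clade,
    candidates_to_tsv,
    clade_frequencies,
    clade_samples,
    dedup_known,
    focal_restricted,
    format_mutation,
    screen,
)
from cladescreen.simulate import SimConfig, simulate_cohort
from cladescreen.tree import MarkerDef
from cladescreen.variantio import MISSING

from conftest import TOY_SAMPLES
from helpers import CHROM, make_matrix

LAX = ScreenConfig(min_call_fraction=0.5)


def row(codes):
    return np.array(codes, dtype=np.int8)


def toy_variant(codes, pos=700, ref="AT", alt="A"):
    return make_matrix([(pos, ref, alt, codes)], TOY_SAMPLES)


# -- clade_samples --------------------------------------------------------

def test_clade_samples_toy(toy_tree, toy_calls):
    assert clade_samples(toy_tree, toy_calls, "O1") == {"s3", "s4", "s5"}
    assert clade_samples(toy_tree, toy_calls, "Y") == set(TOY_SAMPLES)
    with pytest.raises(ValidationError):
        clade_samples(toy_tree, toy_calls, "XX")


def test_clade_samples_matches_simulator_census():
    result = simulate_cohort(SimConfig(seed=11, n_focal_nodes=15, clade_perfect=1))
    calls = dict(zip(result.calls_truth["sample"], result.calls_truth["true_node"]))
    for node in result.tree.nodes:
        expected = {s for s, n in calls.items()
                    if n in result.tree.descendants(node)}
        assert clade_samples(result.tree, calls, node) == expected


# -- clade_frequencies ----------------------------------------------------

def test_frequencies_by_direct_counting(toy_tree, toy_calls):
    matrix = toy_variant([0, 0, 1, 1, 1, 0])
    freqs = clade_frequencies(matrix, toy_calls, toy_tree)
    by_clade = freqs.set_index("clade")
    assert by_clade.loc["O1", "derived_count"] == 3
    assert by_clade.loc["O1", "frequency"] == 1.0
    assert by_clade.loc["O2", "derived_count"] == 0
    assert by_clade.loc["O2", "called_count"] == 1


def test_frequencies_exclude_missing_calls(toy_tree, toy_calls):
    matrix = toy_variant([0, 0, 1, 1, MISSING, 0])
    by_clade = clade_frequencies(matrix, toy_calls, toy_tree).set_index("clade")
    assert by_clade.loc["O1", "called_count"] == 2
    assert by_clade.loc["O1", "frequency"] == 1.0


def test_frequency_row_omitted_when_nothing_called(toy_tree, toy_calls):
    matrix = toy_variant([MISSING, MISSING, 1, 1, 1, 0])
    freqs = clade_frequencies(matrix, toy_calls, toy_tree)
    assert "N" not in set(freqs["clade"])


def test_root_count_conservation_over_random_cohorts():
    result = simulate_cohort(SimConfig(seed=5, n_focal_nodes=12, clade_perfect=4,
                                       incomplete=3, leaky=3))
    calls = dict(zip(result.calls_truth["sample"], result.calls_truth["true_node"]))
    tree = result.tree
    # rebuild a matrix from the planted truth via the VCF text
    from cladescreen.variantio import build_matrix, read_vcf
    import tempfile, pathlib
    d = pathlib.Path(tempfile.mkdtemp())
    (d / "c.vcf").write_text(result.vcf_text)
    samples, records = read_vcf(str(d / "c.vcf"))
    matrix = build_matrix(records, samples)
    freqs = clade_frequencies(matrix, calls, tree)
    root = tree.root
    root_direct = [s for s, n in calls.items() if n == root]
    spos = matrix.sample_index()
    for key, group in freqs.groupby("variant_key"):
        by_clade = group.set_index("clade")["derived_count"]
        i = list(matrix.variants).index(tuple(
            [key.split(":")[0], int(key.split(":")[1]), *key.split(":")[2:]]))
        direct = int(np.count_nonzero(
            matrix.calls[i][[spos[s] for s in root_direct]] == 1))
        child_sum = sum(int(by_clade.get(c, 0))
                        for c in tree.nodes[root].children)
        assert by_clade[root] == child_sum + direct


# -- focal_restricted -----------------------------------------------------

def focal_set(tree, calls):
    return clade_samples(tree, calls, "O")


def test_focal_alt_confined(toy_tree, toy_calls):
    orientation, reason = focal_restricted(row([0, 0, 1, 1, 1, 0]), TOY_SAMPLES,
                                           focal_set(toy_tree, toy_calls))
    assert (orientation, reason) == ("ALT", "ok")


def test_focal_outgroup_carrier_is_none(toy_tree, toy_calls):
    orientation, reason = focal_restricted(row([1, 0, 0, 0, 0, 0]), TOY_SAMPLES,
                                           focal_set(toy_tree, toy_calls))
    assert (orientation, reason) == ("NONE", "not-focal")


def test_focal_ref_orientation_by_allele_swap(toy_tree, toy_calls):
    # swap of the ALT-confined case: outgroup fixed for ALT, O carries REF
    orientation, reason = focal_restricted(row([1, 1, 0, 0, 0, 1]), TOY_SAMPLES,
                                           focal_set(toy_tree, toy_calls))
    assert (orientation, reason) == ("REF", "ok")


def test_focal_low_call_gate(toy_tree, toy_calls):
    orientation, reason = focal_restricted(row([MISSING, 0, 1, 1, 1, 0]),
                                           TOY_SAMPLES,
                                           focal_set(toy_tree, toy_calls),
                                           min_call_fraction=0.9)
    assert (orientation, reason) == ("NONE", "low-call")


# -- assign_clade ---------------------------------------------------------

def _assign(toy_tree, toy_calls, codes, orientation="ALT", config=LAX):
    matrix = toy_variant(codes)
    return assign_clade(matrix.calls[0], TOY_SAMPLES, orientation, toy_calls,
                        toy_tree, config, key=matrix.variants[0])


def test_assign_clade_accepts_exact_clade(toy_tree, toy_calls):
    cand = _assign(toy_tree, toy_calls, [0, 0, 1, 1, 1, 0])
    assert isinstance(cand, CandidateMarker)
    assert cand.assigned_clade == "O1"
    assert cand.carriers == cand.clade_called == 3
    assert cand.outside_derived == 0


def test_assign_clade_criterion1_rejection(toy_tree, toy_calls):
    out = _assign(toy_tree, toy_calls, [0, 0, 1, 0, 1, 0])  # s4 ancestral inside O1
    assert isinstance(out, Rejection) and out.reason == "criterion1"


def test_assign_clade_homoplasy_rejected_at_lca(toy_tree, toy_calls):
    out = _assign(toy_tree, toy_calls, [0, 0, 1, 1, 0, 1])  # D={s3,s4,s6}, C*=O
    assert isinstance(out, Rejection) and out.reason == "criterion1"


def test_assign_clade_empty_carriers_is_contract_violation(toy_tree, toy_calls):
    with pytest.raises(ContractError):
        _assign(toy_tree, toy_calls, [0, 0, 0, 0, 0, 0])


def test_assign_clade_strict_missing_unverifiable(toy_tree, toy_calls):
    strict = ScreenConfig(min_call_fraction=0.5, strict_missing=True)
    out = _assign(toy_tree, toy_calls, [0, 0, 1, MISSING, 1, 0], config=strict)
    assert isinstance(out, Rejection) and out.reason == "unverifiable"
    lax = _assign(toy_tree, toy_calls, [0, 0, 1, MISSING, 1, 0])
    assert isinstance(lax, CandidateMarker) and lax.clade_called == 2


def test_assign_clade_matches_bruteforce_over_all_subsets(toy_tree, toy_calls):
    """Exactly the carrier sets equal to some clade's sample set are accepted."""
    clade_sets = {node: frozenset(clade_samples(toy_tree, toy_calls, node))
                  for node in toy_tree.nodes}
    for bits in itertools.product([0, 1], repeat=6):
        if not any(bits):
            continue
        carriers = frozenset(s for s, b in zip(TOY_SAMPLES, bits) if b)
        out = _assign(toy_tree, toy_calls, list(bits))
        expected = [n for n, members in clade_sets.items() if members == carriers]
        if expected:
            assert isinstance(out, CandidateMarker)
            assert out.assigned_clade == expected[0]
        else:
            assert isinstance(out, Rejection)


def test_singleton_clade_allowed_but_low_evidence(toy_tree, toy_calls):
    cand = _assign(toy_tree, toy_calls, [0, 0, 0, 0, 1, 0])  # O1b census 1
    assert isinstance(cand, CandidateMarker)
    assert cand.assigned_clade == "O1b" and cand.low_evidence


# -- dedup_known ----------------------------------------------------------

KNOWN = [MarkerDef("M175", "O", 700, "AT", "A")]


def make_candidate(pos=700, ref="AT", alt="A"):
    return CandidateMarker(key=(CHROM, pos, ref, alt), id=None,
                           assigned_clade="O", derived_is="ALT", carriers=4,
                           clade_called=4, outside_derived=0)


def test_dedup_marks_identical_site():
    cands = dedup_known([make_candidate()], KNOWN)
    assert cands[0].status == "duplicate_of:M175"


def test_dedup_matches_swapped_allele_order():
    cands = dedup_known([make_candidate(ref="A", alt="AT")], KNOWN)
    assert cands[0].status == "duplicate_of:M175"


def test_dedup_unlisted_position_stays_novel():
    cands = dedup_known([make_candidate(pos=999)], KNOWN)
    assert cands[0].status == "novel"


def test_dedup_same_position_different_alleles_stays_novel():
    cands = dedup_known([make_candidate(ref="ATT", alt="A")], KNOWN)
    assert cands[0].status == "novel"


# -- screen ---------------------------------------------------------------

def toy_screen_matrix():
    return make_matrix([
        (700, "AT", "A", [0, 0, 1, 1, 0, 0]),   # clade-exact for O1a
        (800, "C", "CA", [1, 0, 1, 1, 0, 0]),   # leaky into the outgroup
        (900, "G", "GT", [1, 0, 0, 0, 0, 0]),   # outgroup-only variation
    ], TOY_SAMPLES)


def test_screen_toy_counters(toy_tree, toy_calls):
    result = screen(toy_screen_matrix(), toy_calls, toy_tree, LAX)
    assert result.counters == {"records_seen": 3, "biallelic_indels": 3,
                               "focal_restricted": 1, "clade_exact": 1,
                               "novel": 1}
    assert result.novel[0].assigned_clade == "O1a"


def test_screen_counters_non_increasing(toy_tree, toy_calls):
    counters = screen(toy_screen_matrix(), toy_calls, toy_tree, LAX).counters
    values = list(counters.values())
    assert values == sorted(values, reverse=True)


def test_screen_unknown_focal_clade_is_config_error(toy_tree, toy_calls):
    with pytest.raises(ConfigError):
        screen(toy_screen_matrix(), toy_calls, toy_tree,
               ScreenConfig(focal_clade="ZZ"))


def test_allele_relabel_invariance(toy_tree, toy_calls):
    matrix = toy_screen_matrix()
    swapped_rows = []
    for (_, pos, ref, alt), codes in zip(matrix.variants, matrix.calls):
        flipped = [MISSING if c == MISSING else 1 - c for c in codes.tolist()]
        swapped_rows.append((pos, alt, ref, flipped))
    swapped = make_matrix(swapped_rows, TOY_SAMPLES)
    a = screen(matrix, toy_calls, toy_tree, LAX)
    b = screen(swapped, toy_calls, toy_tree, LAX)
    assert [(c.key[1], c.assigned_clade, c.carriers) for c in a.novel] == \
           [(c.key[1], c.assigned_clade, c.carriers) for c in b.novel]
    assert {c.derived_is for c in a.novel} == {"ALT"}
    assert {c.derived_is for c in b.novel} == {"REF"}


def test_spoiler_monotonicity(toy_tree, toy_calls):
    base = [0, 0, 1, 1, 0, 0]
    assert len(screen(toy_variant(base), toy_calls, toy_tree, LAX).novel) == 1
    for spoiler in (0, 1, 4, 5):  # any added carrier outside O1a
        codes = list(base)
        codes[spoiler] = 1
        result = screen(toy_variant(codes), toy_calls, toy_tree, LAX)
        # the O1a candidacy is always destroyed ...
        assert all(c.assigned_clade != "O1a" for c in result.novel)
        if spoiler != 4:
            assert len(result.novel) == 0
        else:
            # ... but adding s5 completes clade O1 exactly: re-assigned, not novel-for-O1a
            assert [c.assigned_clade for c in result.novel] == ["O1"]


def test_subset_monotonicity_removing_noncarrier(toy_tree, toy_calls):
    matrix = toy_variant([0, 0, 1, 1, 0, 0])
    full = screen(matrix, toy_calls, toy_tree, LAX)
    assert [c.assigned_clade for c in full.novel] == ["O1a"]
    keep = [s for s in TOY_SAMPLES if s != "s6"]
    sub = make_matrix([(700, "AT", "A", [0, 0, 1, 1, 0])], keep)
    calls = {s: n for s, n in toy_calls.items() if s != "s6"}
    reduced = screen(sub, calls, toy_tree, LAX)
    assert [c.assigned_clade for c in reduced.novel] == ["O1a"]


def test_candidates_sorted_by_depth_then_position(toy_tree, toy_calls):
    matrix = make_matrix([
        (900, "AT", "A", [0, 0, 1, 1, 0, 0]),   # O1a, depth 3
        (800, "C", "CA", [0, 0, 1, 1, 1, 1]),   # O, depth 1
        (700, "G", "GT", [0, 0, 1, 1, 1, 0]),   # O1, depth 2
    ], TOY_SAMPLES)
    result = screen(matrix, toy_calls, toy_tree, LAX)
    assert [(c.assigned_clade, c.key[1]) for c in result.candidates] == \
           [("O", 800), ("O1", 700), ("O1a", 900)]


# -- reporting helpers ----------------------------------------------------

@pytest.mark.parametrize("ref,alt,derived_is,expected", [
    ("CTAAAG", "C", "ALT", "TAAAG > -"),
    ("C", "CT", "ALT", "- > T"),
    ("C", "CT", "REF", "T > -"),
    ("CTAAAG", "C", "REF", "- > TAAAG"),
])
def test_format_mutation(ref, alt, derived_is, expected):
    assert format_mutation(ref, alt, derived_is) == expected


def test_candidates_tsv_layout():
    text = candidates_to_tsv([make_candidate()])
    lines = text.strip().split("\n")
    assert lines[0].startswith("variant_key\trsid")
    assert lines[1].split("\t")[3] == "T > -"
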