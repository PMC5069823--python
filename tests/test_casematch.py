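import itertools
import random

import pytest

from somatrack.casematch import (
    SomaticSet,
    classify_metastasis,
    compare_colocated_lesions,
    derive_de_novo,
    is_ras_hotspot,
    partition_shared,
    somatic_sets_for_case,
    subtract_germline,
    track_ras,
)
from somatrack.errors import (
    CaseMismatchError,
    DomainError,
    IncompleteCaseError,
    ValidationError,
)
from somatrack.model import (
    Case,
    DetectionStatus,
    FilterConfig,
    MetastasisTiming,
    Specimen,
    Tissue,
    Variant,
    YearMonth,
)

from conftest import make_call, make_case, make_variant

CFG = FilterConfig()


def sset(sid, *gene_hgvs, af=50.0):
    return SomaticSet.from_calls(
        sid, [make_call(sid, gene=g, hgvs_p=h, af=af) for g, h in gene_hgvs]
    )


# --------------------------------------------------------------------------- #
# subtract_germline


def test_self_subtraction_is_empty():
    tumour = [make_call("t", gene="APC", hgvs_p="p.Q1338*"),
              make_call("t", gene="TP53", hgvs_p="p.R175H")]
    normal = [make_call("n", gene="APC", hgvs_p="p.Q1338*"),
              make_call("n", gene="TP53", hgvs_p="p.R175H")]
    assert len(subtract_germline(tumour, normal, CFG)) == 0


def test_planted_germline_removed_somatic_kept():
    germline = [(f"G{i}", f"p.A{i}B") for i in range(5)]
    somatic = [("KRAS", "p.G12D"), ("TP53", "p.R175H"), ("APC", "p.Q1338*")]
    tumour = [make_call("t", gene=g, hgvs_p=h) for g, h in germline + somatic]
    normal = [make_call("n", gene=g, hgvs_p=h) for g, h in germline]
    out = subtract_germline(tumour, normal, CFG)
    assert out.keys == {("p", g, h) for g, h in somatic}


def test_low_evidence_normal_call_does_not_subtract():
    tumour = [make_call("t", gene="KRAS", hgvs_p="p.G12D", af=40.0)]
    noise = [make_call("n", gene="KRAS", hgvs_p="p.G12D", af=0.5)]  # < rescue
    assert len(subtract_germline(tumour, noise, CFG)) == 1
    real = [make_call("n", gene="KRAS", hgvs_p="p.G12D", af=1.0)]  # >= rescue
    assert len(subtract_germline(tumour, real, CFG)) == 0


def test_germline_matching_ignores_allele_fraction():
    tumour = [make_call("t", gene="APC", hgvs_p="p.Q1338*", af=90.0)]
    normal = [make_call("n", gene="APC", hgvs_p="p.Q1338*", af=12.0)]
    assert len(subtract_germline(tumour, normal, CFG)) == 0


def test_cross_case_subtraction_raises():
    a = Specimen("t", "caseA", Tissue.PRIMARY, resection_date=YearMonth(2010, 1))
    b = Specimen("n", "caseB", Tissue.NORMAL)
    with pytest.raises(CaseMismatchError):
        subtract_germline([], [], CFG, tumour_specimen=a, normal_specimen=b)


def test_blacklisted_variant_already_absent():
    # TP53 p.P72R is removed by the filter stack upstream; subtraction of a
    # normal set containing it must not resurrect or disturb anything.
    tumour = [make_call("t", gene="KRAS", hgvs_p="p.G12D")]
    normal = [make_call("n", gene="TP53", hgvs_p="p.P72R")]
    out = subtract_germline(tumour, normal, CFG)
    assert out.keys == {("p", "KRAS", "p.G12D")}


def test_duplicate_keys_rejected():
    with pytest.raises(ValidationError, match="duplicate"):
        SomaticSet.from_calls("s", [make_call("s"), make_call("s")])


# --------------------------------------------------------------------------- #
# classify_metastasis


def _met(months_offset, case_id="c", tissue=Tissue.LIVER_MET):
    base = YearMonth(2004, 3)
    total = base.year * 12 + base.month - 1 + months_offset
    return Specimen(
        "m", case_id, tissue,
        resection_date=YearMonth(total // 12, total % 12 + 1),
    )


def test_two_months_later_is_synchronous():
    # primary 2004-03, liver met 2004-05
    assert classify_metastasis(_met(2), YearMonth(2004, 3)) \
        is MetastasisTiming.SYNCHRONOUS


def test_same_month_is_synchronous():
    assert classify_metastasis(_met(0), YearMonth(2004, 3)) \
        is MetastasisTiming.SYNCHRONOUS


def test_ten_months_later_is_metachronous():
    # primary 2005-04, lung met 2006-02
    sp = Specimen("m", "c", Tissue.LUNG_MET, resection_date=YearMonth(2006, 2))
    assert classify_metastasis(sp, YearMonth(2005, 4)) \
        is MetastasisTiming.METACHRONOUS


def test_six_month_boundary_is_strict():
    assert classify_metastasis(_met(6), YearMonth(2004, 3)) \
        is MetastasisTiming.SYNCHRONOUS
    assert classify_metastasis(_met(7), YearMonth(2004, 3)) \
        is MetastasisTiming.METACHRONOUS


def test_earlier_resection_is_synchronous():
    assert classify_metastasis(_met(-5), YearMonth(2004, 3)) \
        is MetastasisTiming.SYNCHRONOUS


def test_classification_rejects_non_metastasis():
    sp = Specimen("p", "c", Tissue.PRIMARY, resection_date=YearMonth(2004, 3))
    with pytest.raises(DomainError):
        classify_metastasis(sp, YearMonth(2004, 3))


# --------------------------------------------------------------------------- #
# partition_shared


def test_all_shared_gives_truncal_three():
    case = make_case("c14", n_mets=2)
    trio = [("APC", "p.T1430Pfs*"), ("NRAS", "p.Q61R"), ("TP53", "p.R175H")]
    somatic = {
        sid: sset(sid, *trio)
        for sid in ("c14_PT", "c14_M1", "c14_M2")
    }
    part = partition_shared(case, somatic)
    assert len(part.truncal) == 3
    assert not part.other_shared
    assert all(not s for s in part.private.values())


def test_partially_shared_goes_to_other_shared():
    case = make_case("c1", n_mets=2)
    kras = ("KRAS", "p.G12D")
    tp53 = ("TP53", "p.R342*")
    somatic = {
        "c1_PT": sset("c1_PT", kras, tp53),
        "c1_M1": sset("c1_M1", kras),  # TP53 wildtype here
        "c1_M2": sset("c1_M2", kras, tp53),
    }
    part = partition_shared(case, somatic)
    assert part.truncal == {("p", *kras)}
    assert ("p", *tp53) in part.other_shared
    assert part.other_shared[("p", *tp53)] == frozenset({"c1_PT", "c1_M2"})


def test_missing_specimen_raises_naming_it():
    case = make_case("x", n_mets=2)
    somatic = {"x_PT": sset("x_PT"), "x_M1": sset("x_M1")}
    with pytest.raises(IncompleteCaseError, match="x_M2"):
        partition_shared(case, somatic)


def _enumerate_oracle(case, somatic):
    """Independent oracle: enumerate support subsets per key."""
    sids = [s.specimen_id for s in case.tumour_specimens]
    all_keys = set().union(*(somatic[s].keys for s in sids))
    truncal, private, other = set(), {s: set() for s in sids}, {}
    for key in all_keys:
        support = frozenset(s for s in sids if key in somatic[s])
        for size in range(1, len(sids) + 1):
            for combo in itertools.combinations(sids, size):
                if frozenset(combo) == support:
                    if size == len(sids):
                        truncal.add(key)
                    elif size == 1:
                        private[combo[0]].add(key)
                    else:
                        other[key] = support
    return truncal, private, other


def test_random_case_matches_subset_enumeration_oracle():
    rng = random.Random(5)
    for trial in range(20):
        case = make_case(f"r{trial}", n_mets=3)
        sids = [s.specimen_id for s in case.tumour_specimens]
        pool = [(f"G{i}", f"p.A{i}V") for i in range(8)]
        somatic = {
            sid: sset(sid, *[gv for gv in pool if rng.random() < 0.5])
            for sid in sids
        }
        part = partition_shared(case, somatic)
        truncal, private, other = _enumerate_oracle(case, somatic)
        assert part.truncal == truncal
        assert part.private == private
        assert part.other_shared == other


def test_partition_invariant_disjoint_union(sim_result):
    cfg = CFG
    from somatrack.filtering import filter_calls

    filtered = {sid: filter_calls(c, cfg) for sid, c in sim_result.calls.items()}
    for case in sim_result.manifest.cases:
        somatic = somatic_sets_for_case(case, filtered, cfg)
        part = partition_shared(case, somatic)
        privates = set().union(*part.private.values()) if part.private else set()
        assert part.truncal.isdisjoint(privates)
        assert part.truncal.isdisjoint(part.other_shared)
        assert privates.isdisjoint(part.other_shared)
        union = part.truncal | privates | set(part.other_shared)
        assert union == set().union(*(s.keys for s in somatic.values()))


# --------------------------------------------------------------------------- #
# derive_de_novo


def test_identical_met_and_primary_gives_empty():
    a = sset("m", ("KRAS", "p.G12D"), ("TP53", "p.R175H"))
    b = sset("p", ("KRAS", "p.G12D"), ("TP53", "p.R175H"))
    assert derive_de_novo(a, b) == set()


def test_planted_private_on_trunk():
    trunk = [("KRAS", "p.G12D"), ("TP53", "p.R175H")]
    private = [(f"G{i}", f"p.Q{i}*") for i in range(4)]
    met = sset("m", *(trunk + private))
    primary = sset("p", *trunk)
    assert derive_de_novo(met, primary) == {("p", g, h) for g, h in private}


def test_met_only_variant_detected():
    met = sset("m", ("KRAS", "p.G12V"), ("SMO", "p.T640A"))
    primary = sset("p", ("KRAS", "p.G12V"))
    assert ("p", "SMO", "p.T640A") in derive_de_novo(met, primary)


def test_strict_mode_also_subtracts_rescue_set():
    met = sset("m", ("KRAS", "p.G12V"), ("SMO", "p.T640A"))
    primary = sset("p", ("KRAS", "p.G12V"))
    rescue = sset("p", ("KRAS", "p.G12V"), ("SMO", "p.T640A"), af=3.0)
    standard = derive_de_novo(met, primary)
    strict = derive_de_novo(met, primary, primary_rescue=rescue)
    assert strict <= standard
    assert ("p", "SMO", "p.T640A") not in strict


def test_cross_case_de_novo_raises():
    a = Specimen("m", "A", Tissue.LIVER_MET, resection_date=YearMonth(2010, 1))
    b = Specimen("p", "B", Tissue.PRIMARY, resection_date=YearMonth(2010, 1))
    with pytest.raises(CaseMismatchError):
        derive_de_novo(sset("m"), sset("p"), met_specimen=a, primary_specimen=b)


def test_subset_disjoint_invariants():
    rng = random.Random(9)
    pool = [(f"G{i}", f"p.A{i}V") for i in range(10)]
    for _ in range(25):
        met = sset("m", *[gv for gv in pool if rng.random() < 0.6])
        primary = sset("p", *[gv for gv in pool if rng.random() < 0.6])
        dn = derive_de_novo(met, primary)
        assert dn <= met.keys
        assert dn.isdisjoint(primary.keys)
        # de_novo and (met ∩ primary) partition the met set
        assert dn | (met.keys & primary.keys) == met.keys
        assert dn.isdisjoint(met.keys & primary.keys)


# --------------------------------------------------------------------------- #
# track_ras


def test_hotspot_definition():
    assert is_ras_hotspot(make_variant("KRAS", "p.G12D"))
    assert is_ras_hotspot(make_variant("KRAS", "p.G13D"))
    assert is_ras_hotspot(make_variant("NRAS", "p.Q61R"))
    assert is_ras_hotspot(make_variant("KRAS", "p.A59T"))
    assert is_ras_hotspot(make_variant("KRAS", "p.K117N"))
    assert is_ras_hotspot(make_variant("KRAS", "p.A146T"))
    assert not is_ras_hotspot(make_variant("KRAS", "p.L19F"))
    assert not is_ras_hotspot(make_variant("BRAF", "p.V600E"))


def _ras_case_from_reference(ref_manifest, ras_calls, case_id):
    case = ref_manifest.case(case_id)
    return track_ras(case, ras_calls, CFG)


def test_maintained_case_all_detected(ref_manifest, ras_calls):
    traj = _ras_case_from_reference(ref_manifest, ras_calls, "01")
    assert traj.primary_status == "mutated"
    assert traj.maintained
    [track] = traj.ras_variants
    assert track.variant.gene == "KRAS" and track.variant.hgvs_p == "p.G12D"
    assert track.af_by_specimen["c01_PT"] == pytest.approx(55.59)
    assert track.af_by_specimen["c01_synHEP_1"] == pytest.approx(97.28)
    assert track.af_by_specimen["c01_metPUL_1"] == pytest.approx(16.77)
    assert all(
        s is DetectionStatus.DETECTED for s in track.status_by_specimen.values()
    )


def test_sub_threshold_lesion_flagged_but_maintained(ref_manifest, ras_calls):
    traj = _ras_case_from_reference(ref_manifest, ras_calls, "05")
    assert traj.primary_status == "mutated"
    assert traj.maintained
    [track] = traj.ras_variants
    assert track.status_by_specimen["c05_synHEP_1"] \
        is DetectionStatus.DETECTED_BELOW_THRESHOLD
    assert traj.sub_threshold_specimens == ["c05_synHEP_1"]


def test_lost_variant_case_not_maintained(ref_manifest, ras_calls):
    for case_id, missing in [("03", "c03_metPUL_1"), ("06", "c06_metHEP_1")]:
        traj = _ras_case_from_reference(ref_manifest, ras_calls, case_id)
        assert traj.primary_status == "mutated"
        assert not traj.maintained
        [track] = traj.ras_variants
        assert track.status_by_specimen[missing] is DetectionStatus.NOT_DETECTED


def test_allele_switch_case_counts_as_maintained(ref_manifest, ras_calls):
    # primary carries one codon-12 allele; lesions carry another hotspot
    # allele -- tracked independently, case-level status still maintained
    traj = _ras_case_from_reference(ref_manifest, ras_calls, "13")
    assert traj.primary_status == "mutated"
    assert traj.maintained
    genes = {(t.variant.gene, t.variant.hgvs_p) for t in traj.ras_variants}
    assert genes == {("KRAS", "p.G12D"), ("KRAS", "p.G12V")}
    assert "c13_synPUL_1" in traj.sub_threshold_specimens


def test_wildtype_case_has_no_trajectory_rows(ref_manifest, ras_calls):
    traj = _ras_case_from_reference(ref_manifest, ras_calls, "04")
    assert traj.primary_status == "wildtype"
    assert traj.ras_variants == []
    assert not traj.maintained


def test_maintained_insensitive_to_af_fluctuation_above_rescue():
    case = make_case("c", n_mets=2)
    rng = random.Random(2)
    for _ in range(20):
        calls = {
            sid: [make_call(sid, gene="KRAS", hgvs_p="p.G12D",
                            af=rng.uniform(1.0, 100.0))]
            for sid in ("c_PT", "c_M1", "c_M2")
        }
        # force a mutated primary at standard cutoff
        calls["c_PT"] = [make_call("c_PT", gene="KRAS", hgvs_p="p.G12D",
                                   af=rng.uniform(10.0, 100.0))]
        traj = track_ras(case, calls, CFG)
        assert traj.maintained


def test_track_ras_requires_primary():
    bad = Case(
        case_id="b",
        specimens=[
            Specimen("b_N", "b", Tissue.NORMAL),
            Specimen("b_M1", "b", Tissue.LIVER_MET,
                     resection_date=YearMonth(2010, 2)),
        ],
    )
    with pytest.raises(ValidationError):
        track_ras(bad, {}, CFG)


# --------------------------------------------------------------------------- #
# compare_colocated_lesions


def _colocated_case():
    d = YearMonth(2014, 2)
    case = Case(
        case_id="cc",
        specimens=[
            Specimen("cc_N", "cc", Tissue.NORMAL),
            Specimen("cc_PT", "cc", Tissue.PRIMARY, resection_date=d),
            Specimen("cc_A", "cc", Tissue.LIVER_MET, lesion_label="segment 5",
                     resection_date=d),
            Specimen("cc_B", "cc", Tissue.LIVER_MET, lesion_label="segment 7",
                     resection_date=d),
        ],
    )
    case.validate()
    return case


def test_identical_profiles_have_empty_exclusives():
    case = _colocated_case()
    trio = [("APC", "p.T1430Pfs*"), ("NRAS", "p.Q61R"), ("TP53", "p.R175H")]
    rec = compare_colocated_lesions(case, sset("cc_A", *trio), sset("cc_B", *trio))
    assert rec.n_shared == 3
    assert rec.exclusive_a == set() and rec.exclusive_b == set()


def test_disjoint_toy_sets():
    case = _colocated_case()
    rec = compare_colocated_lesions(
        case,
        sset("cc_A", ("A", "p.A1V"), ("B", "p.B2V")),
        sset("cc_B", ("C", "p.C3V")),
    )
    assert rec.shared == set()
    assert rec.counts == (0, 2, 1)


def test_random_pairs_match_set_oracle():
    case = _colocated_case()
    rng = random.Random(13)
    pool = [(f"G{i}", f"p.A{i}V") for i in range(12)]
    for _ in range(30):
        a = [gv for gv in pool if rng.random() < 0.5]
        b = [gv for gv in pool if rng.random() < 0.5]
        rec = compare_colocated_lesions(case, sset("cc_A", *a), sset("cc_B", *b))
        ka = {("p", g, h) for g, h in a}
        kb = {("p", g, h) for g, h in b}
        assert rec.shared == ka & kb
        assert rec.exclusive_a == ka - kb
        assert rec.exclusive_b == kb - ka
        assert len(rec.shared) + len(rec.exclusive_a) == len(ka)


def test_colocated_mismatch_errors():
    d = YearMonth(2014, 2)
    case = Case(
        case_id="cc",
        specimens=[
            Specimen("cc_N", "cc", Tissue.NORMAL),
            Specimen("cc_PT", "cc", Tissue.PRIMARY, resection_date=d),
            Specimen("cc_A", "cc", Tissue.LIVER_MET, resection_date=d),
            Specimen("cc_B", "cc", Tissue.LUNG_MET, resection_date=d),
            Specimen("cc_C", "cc", Tissue.LIVER_MET,
                     resection_date=YearMonth(2014, 6)),
        ],
    )
    with pytest.raises(CaseMismatchError, match="tissue"):
        compare_colocated_lesions(case, sset("cc_A"), sset("cc_B"))
    with pytest.raises(CaseMismatchError, match="date"):
        compare_colocated_lesions(case, sset("cc_A"), sset("cc_C"))
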