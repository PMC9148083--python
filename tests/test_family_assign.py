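import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from skbio import TreeNode

from cyp_repertoire.family_assign import (
    AlignParams,
    assign,
    assign_all,
    build_tree,
    percent_identity,
)
from cyp_repertoire.p450_detect import classify
from cyp_repertoire.sequence_io import PanelEntry, ProteinRecord, ReferencePanel
from cyp_repertoire.synthetic_data import (
    SynthConfig,
    _plant_motifs,
    _random_sequence,
    make_panel,
    mutate_to_identity,
)

from conftest import make_p450_like


# --------------------------------------------------------------------------
# percent identity

def test_identical_sequences_are_100_percent():
    seq = _random_sequence(np.random.default_rng(0), 400)
    assert percent_identity(seq, seq).percent_identity == 100.0


def test_single_substitution_pair():
    # diagonal alignment, 9 identical of 10 columns
    r = percent_identity("ACDEFGHIKL", "ACDEFGHIKV")
    assert r.percent_identity == pytest.approx(90.0)
    assert r.aligned_length == 10


def test_empty_sequence_errors():
    with pytest.raises(ValueError, match="empty"):
        percent_identity("", "ACDEF")


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    a=st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=40),
    b=st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=40),
)
def test_identity_symmetry_property(a, b):
    pid_ab = percent_identity(a, b).percent_identity
    pid_ba = percent_identity(b, a).percent_identity
    assert pid_ab == pid_ba
    assert 0.0 <= pid_ab <= 100.0


def test_shorter_sequence_denominator():
    params = AlignParams(denominator="shorter-sequence")
    r = percent_identity("ACDEFGHIKL", "ACDEFGHIKL" + "WWWWW", params)
    assert r.percent_identity == pytest.approx(100.0)


# --------------------------------------------------------------------------
# assignment rule

def _as_candidate(protein_id, species_id, seq):
    return classify(ProteinRecord(protein_id, species_id, seq))


def test_assign_exact_match_recovers_family_and_subfamily(small_panel):
    panel, seeds, _ = small_panel
    entry = panel.entries[0]
    cand = _as_candidate("q1", "sp1", entry.sequence)
    a = assign(cand, panel)
    assert a.family_name == entry.family_name
    assert a.subfamily_name == entry.subfamily_name
    assert a.best_ref_id == entry.ref_id
    assert a.best_identity == pytest.approx(100.0)
    assert not a.is_novel_family and not a.is_novel_subfamily


def test_assign_midrange_identity_yields_novel_subfamily(small_panel):
    panel, seeds, anchors = small_panel
    fam = sorted(seeds)[0]
    u, v = anchors[fam]
    rng = np.random.default_rng(5)
    # planted 45±3% sits strictly inside the (40, 55] family-only band
    seq = mutate_to_identity(seeds[fam], 45.0, rng, protected=(u, u + 3, v, v + 2))
    a = assign(_as_candidate("q1", "sp1", seq), panel)
    assert a.family_name == fam
    assert not a.is_novel_family
    assert a.is_novel_subfamily
    assert a.subfamily_name.startswith(fam)
    assert a.subfamily_name != f"{fam}A"


def test_assign_distant_query_founds_new_family(small_panel):
    panel, seeds, anchors = small_panel
    fam = sorted(seeds)[0]
    u, v = anchors[fam]
    rng = np.random.default_rng(6)
    seq = mutate_to_identity(seeds[fam], 30.0, rng, protected=(u, u + 3, v, v + 2))
    a = assign(_as_candidate("q1", "sp1", seq), panel)
    assert a.is_novel_family
    assert a.family_name == "NEWFAM1"
    assert a.subfamily_name == "NEWFAM1A"


def test_thresholds_are_strict_at_the_boundary(small_panel):
    """Exactly at a threshold falls below it (rule is >, not >=)."""
    panel, seeds, _ = small_panel
    entry = panel.entries[0]
    cand = _as_candidate("q1", "sp1", entry.sequence)  # pid exactly 100.0
    a = assign(cand, panel, subfamily_threshold=100.0)
    assert not a.is_novel_family and a.is_novel_subfamily
    a = assign(cand, panel, family_threshold=100.0, subfamily_threshold=100.0)
    assert a.is_novel_family


def test_assign_empty_panel_errors(small_panel):
    cand = _as_candidate("q1", "sp1", "ACDEF" * 50)
    with pytest.raises(ValueError, match="empty"):
        assign(cand, ReferencePanel(entries=[]))


def test_two_distant_relatives_share_one_new_family(small_panel):
    """Both queries are below 40% to the panel but >40% to each other:
    the second joins the first's NEWFAM via panel augmentation."""
    panel, seeds, _ = small_panel
    rng = np.random.default_rng(21)
    novel_seed, u, v = _plant_motifs(_random_sequence(rng, 400), rng)
    protected = (u, u + 3, v, v + 2)
    q1 = mutate_to_identity(novel_seed, 80.0, rng, protected=protected)
    q2 = mutate_to_identity(novel_seed, 80.0, rng, protected=protected)
    for q in (q1, q2):
        for e in panel.entries:
            assert percent_identity(q, e.sequence).percent_identity <= 40.0
    cands = [_as_candidate("qa", "sp1", q1), _as_candidate("qb", "sp1", q2)]
    assignments, fam_census, _ = assign_all(cands, panel)
    assert [a.family_name for a in assignments] == ["NEWFAM1", "NEWFAM1"]
    assert fam_census["NEWFAM1"] == 2


def test_assign_all_is_input_order_independent(small_panel):
    panel, seeds, anchors = small_panel
    rng = np.random.default_rng(3)
    cands = []
    for i, fam in enumerate(sorted(seeds)):
        u, v = anchors[fam]
        seq = mutate_to_identity(seeds[fam], 70.0, rng, protected=(u, u + 3, v, v + 2))
        cands.append(_as_candidate(f"q{i}", "sp1", seq))
    fwd, _, _ = assign_all(cands, panel)
    rev, _, _ = assign_all(list(reversed(cands)), panel)
    assert fwd == rev


def test_census_sums_to_candidate_count(small_panel):
    panel, seeds, anchors = small_panel
    rng = np.random.default_rng(4)
    fam = sorted(seeds)[1]
    u, v = anchors[fam]
    cands = [
        _as_candidate(f"q{i}", "sp1",
                      mutate_to_identity(seeds[fam], 80.0, rng,
                                         protected=(u, u + 3, v, v + 2)))
        for i in range(3)
    ]
    assignments, fam_census, sub_census = assign_all(cands, panel)
    assert sum(fam_census.values()) == len(cands)
    assert sum(sub_census.values()) == len(cands)
    assert fam_census[fam] == 3


# --------------------------------------------------------------------------
# brute-force oracle equivalence

def brute_force_assign(candidates, panel, fam_thr=40.0, sub_thr=55.0):
    """Straight-line reimplementation: full identity matrix first, then the
    threshold rule applied query by query in sorted order."""
    ordered = sorted(candidates, key=lambda c: (c.record.species_id,
                                                c.record.protein_id))
    refs = [(e.ref_id, e.family_name, e.subfamily_name, e.sequence)
            for e in panel.entries]
    subfams = {}
    for _, fam, sub, _ in refs:
        subfams.setdefault(fam, set()).add(sub[len(fam):])
    n_new = 0
    out = []
    for cand in ordered:
        seq = cand.record.sequence
        pids = [
            (percent_identity(seq, rseq).percent_identity, rid, fam, sub)
            for rid, fam, sub, rseq in refs
        ]
        best = min(pids, key=lambda t: (-t[0], t[1]))
        pid, rid, fam, sub = best
        if pid > sub_thr:
            res = (fam, sub, False, False)
        elif pid > fam_thr:
            letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
            used = subfams.setdefault(fam, set())
            new = next(l for l in letters if l not in used)
            used.add(new)
            res = (fam, fam + new, False, True)
        else:
            n_new += 1
            fam = f"NEWFAM{n_new}"
            subfams[fam] = {"A"}
            res = (fam, fam + "A", True, True)
        refs.append((cand.record.protein_id, res[0], res[1], seq))
        subfams.setdefault(res[0], set()).add(res[1][len(res[0]):])
        out.append((cand.record.protein_id,) + res)
    return out


def _random_instance(rng, n_refs, n_queries, length=150):
    entries = []
    seeds = []
    for i in range(n_refs):
        seq, u, v = _plant_motifs(_random_sequence(rng, length), rng)
        seeds.append((seq, (u, u + 3, v, v + 2)))
        entries.append(PanelEntry(f"CYP{201 + i}A1", f"CYP{201 + i}",
                                  f"CYP{201 + i}A", seq))
    cands = []
    for j in range(n_queries):
        seed, protected = seeds[int(rng.integers(n_refs))]
        target = float(rng.choice([30.0, 45.0, 50.0, 60.0, 80.0]))
        seq = mutate_to_identity(seed, target, rng, protected=protected)
        cands.append(_as_candidate(f"q{j:02d}", "sp1", seq))
    return ReferencePanel(entries=entries), cands


@pytest.mark.parametrize("instance_seed", range(10))
def test_assign_all_matches_brute_force(instance_seed):
    rng = np.random.default_rng(1000 + instance_seed)
    panel, cands = _random_instance(
        rng, n_refs=int(rng.integers(2, 9)), n_queries=int(rng.integers(2, 9))
    )
    assignments, _, _ = assign_all(cands, panel)
    got = [(a.query_id, a.family_name, a.subfamily_name,
            a.is_novel_family, a.is_novel_subfamily) for a in assignments]
    assert got == brute_force_assign(cands, panel)


def test_raising_family_threshold_never_loses_novel_families(small_panel):
    panel, seeds, anchors = small_panel
    rng = np.random.default_rng(9)
    cands = []
    for i in range(6):
        fam = sorted(seeds)[i % len(seeds)]
        u, v = anchors[fam]
        target = [30.0, 50.0, 80.0][i % 3]
        seq = mutate_to_identity(seeds[fam], target, rng,
                                 protected=(u, u + 3, v, v + 2))
        cands.append(_as_candidate(f"q{i}", "sp1", seq))
    counts = []
    for thr in (40.0, 55.0, 70.0):
        assignments, _, _ = assign_all(cands, panel, family_threshold=thr)
        counts.append(sum(a.is_novel_family for a in assignments))
    assert counts == sorted(counts)


# --------------------------------------------------------------------------
# neighbor-joining tree export

def _toy_assignments(seqs):
    panel = ReferencePanel(entries=[PanelEntry("CYP301A1", "CYP301",
                                               "CYP301A", seqs["a"])])
    cands = [_as_candidate(k, "sp1", v) for k, v in seqs.items()]
    assignments, _, _ = assign_all(cands, panel)
    return assignments


def test_tree_three_taxon_distances_recovered():
    """For 3 taxa, NJ branch lengths satisfy the closed form, so patristic
    tip-to-tip distances equal the input identity distances exactly."""
    rng = np.random.default_rng(12)
    base, u, v = _plant_motifs(_random_sequence(rng, 300), rng)
    protected = (u, u + 3, v, v + 2)
    seqs = {
        "a": base,
        "b": mutate_to_identity(base, 80.0, rng, protected=protected),
        "c": mutate_to_identity(base, 50.0, rng, protected=protected),
    }
    assignments = _toy_assignments(seqs)
    d = {
        pair: 1.0 - percent_identity(seqs[pair[0]], seqs[pair[1]]).percent_identity / 100.0
        for pair in (("a", "b"), ("a", "c"), ("b", "c"))
    }
    newick = build_tree(assignments, seqs)
    tree = TreeNode.read([newick])
    tips = {t.name.split("_")[-1]: t for t in tree.tips()}
    assert set(tips) == {"a", "b", "c"}
    for (x, y), dist in d.items():
        assert tips[x].distance(tips[y]) == pytest.approx(dist, abs=1e-9)


def test_tree_identical_pair_forms_cherry():
    rng = np.random.default_rng(13)
    base, u, v = _plant_motifs(_random_sequence(rng, 300), rng)
    far = mutate_to_identity(base, 30.0, rng, protected=(u, u + 3, v, v + 2))
    seqs = {"a": base, "b": base, "c": far}
    assignments = _toy_assignments(seqs)
    tree = TreeNode.read([build_tree(assignments, seqs)])
    tips = {t.name.split("_")[-1]: t for t in tree.tips()}
    assert tips["a"].distance(tips["b"]) == pytest.approx(0.0, abs=1e-9)


def test_tree_requires_three_sequences():
    rng = np.random.default_rng(14)
    base, u, v = _plant_motifs(_random_sequence(rng, 300), rng)
    seqs = {"a": base, "b": mutate_to_identity(base, 80.0, rng,
                                               protected=(u, u + 3, v, v + 2))}
    assignments = _toy_assignments(seqs)
    with pytest.raises(ValueError, match="3"):
        build_tree(assignments, seqs)
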