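import numpy as np
import pytest

from cdgmine.activity import score_site_conservation
from cdgmine.effectors import find_switch_motifs
from cdgmine.io import write_domain_table, write_fasta
from cdgmine.qpcr import relative_expression
from cdgmine.synth import (
    SyntheticSpec,
    make_ct_table,
    make_domain_variant,
    make_pilz_domain,
    make_synthetic_proteome,
    synthetic_reference_panel,
    write_label_table,
)


def test_panel_generation_is_deterministic():
    a = synthetic_reference_panel()
    b = synthetic_reference_panel()
    assert a.catalytic["EAL"].reference_sequence == b.catalytic["EAL"].reference_sequence
    assert a.pilz.keys() == b.pilz.keys()


def test_zero_mutation_variant_is_the_reference(panel):
    model = panel.catalytic["GGDEF"]
    seq, mutated = make_domain_variant(model, 0, 0.0, np.random.default_rng(1))
    assert seq == model.reference_sequence
    assert mutated == ()


def test_single_mutation_variant_loses_exactly_one_site(panel):
    model = panel.catalytic["GGDEF"]
    seq, mutated = make_domain_variant(model, 1, rng=np.random.default_rng(2))
    v = score_site_conservation(seq, model)
    assert len(mutated) == 1
    assert v.conserved_count == v.total_sites - 1
    assert v.active


def test_two_mutations_cross_the_activity_boundary(panel):
    model = panel.catalytic["GGDEF"]
    seq, _ = make_domain_variant(model, 2, rng=np.random.default_rng(3))
    assert not score_site_conservation(seq, model).active


def test_mutation_count_beyond_sites_errors(panel):
    model = panel.catalytic["GGDEF"]
    with pytest.raises(ValueError):
        make_domain_variant(model, model.total_sites + 1, rng=np.random.default_rng(0))


def test_off_site_mutations_leave_sites_intact(panel):
    model = panel.catalytic["GGDEF"]
    seq, _ = make_domain_variant(model, 0, 0.1, np.random.default_rng(4))
    v = score_site_conservation(seq, model)
    assert v.conserved_count == v.total_sites
    assert seq != model.reference_sequence  # some off-site change happened


def test_indel_variant_keeps_catalytic_sites_recoverable(panel):
    model = panel.catalytic["GGDEF"]
    seq, _ = make_domain_variant(model, 0, 0.0, np.random.default_rng(5), indels=True)
    assert score_site_conservation(seq, model).active


def test_pilz_domains_match_their_labels():
    rng = np.random.default_rng(6)
    for _ in range(5):
        assert find_switch_motifs(make_pilz_domain(rng, True)).binder
        assert not find_switch_motifs(make_pilz_domain(rng, False)).binder


def test_proteome_counts_follow_the_spec(panel):
    spec = SyntheticSpec(seed=7, n_active_dgc=5, n_degenerate_hybrid=3,
                         n_degenerate_dgc=0, n_active_pde=0, n_degenerate_pde=0,
                         n_hybrid_bifunctional=0, n_pilz_binder=2, n_pilz_nonbinder=0)
    records, annotations, labels = make_synthetic_proteome(spec, panel)
    assert len(records) == 10
    by_cat = {}
    for l in labels:
        by_cat[l.category] = by_cat.get(l.category, 0) + 1
    assert by_cat == {"active-DGC": 5, "effector-candidate": 3, "PilZ-binder": 2}


def test_proteome_generation_is_byte_identical_under_seed(tmp_path, panel):
    spec = SyntheticSpec(seed=13, include_accessory=True)
    outputs = []
    for sub in ("a", "b"):
        d = tmp_path / sub
        d.mkdir()
        records, annotations, labels = make_synthetic_proteome(spec, panel)
        write_fasta(records, d / "p.fasta")
        write_domain_table(annotations, d / "d.tsv")
        write_label_table(labels, d / "l.tsv")
        outputs.append(
            tuple((d / n).read_bytes() for n in ("p.fasta", "d.tsv", "l.tsv"))
        )
    assert outputs[0] == outputs[1]


def test_annotation_coordinates_slice_the_built_domains(panel):
    spec = SyntheticSpec(seed=21, include_accessory=True)
    records, annotations, labels = make_synthetic_proteome(spec, panel)
    by_id = {r.id: r for r in records}
    for ann in annotations:
        assert 1 <= ann.start <= ann.end <= len(by_id[ann.protein_id])


def test_ct_table_exact_effects_without_noise():
    table = make_ct_table(["null", "up"], [0.0, 3.0], n_replicates=3, noise_sd=0.0, seed=1)
    assert relative_expression(table, "null").log2_fold_change == 0.0
    assert relative_expression(table, "up").log2_fold_change == pytest.approx(3.0)


def test_ct_table_is_deterministic_under_seed():
    a = make_ct_table(["g"], [1.5], seed=9)
    b = make_ct_table(["g"], [1.5], seed=9)
    assert a.equals(b)


@pytest.mark.parametrize("kwargs", [dict(noise_sd=-1.0), dict(n_replicates=1)])
def test_ct_table_rejects_bad_parameters(kwargs):
    with pytest.raises(ValueError):
        make_ct_table(["g"], [0.0], **{**dict(n_replicates=3, noise_sd=0.1, seed=0), **kwargs})
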