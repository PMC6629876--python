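import numpy as np
import pytest

from cdgmine.activity import (
    ActivityVerdict,
    classify_protein,
    classify_proteome,
    inventory,
    score_site_conservation,
)
from cdgmine.references import CatalyticSite, ReferenceDomainModel
from cdgmine.synth import (
    EXPECTED_CATEGORY,
    SyntheticSpec,
    make_domain_variant,
    make_synthetic_proteome,
)


def _mutate(model, positions):
    """Break the given catalytic sites to a residue outside the allowed set."""
    seq = list(model.reference_sequence)
    by_pos = {s.position: s for s in model.catalytic_sites}
    for pos in positions:
        site = by_pos[pos]
        seq[pos - 1] = "W" if "W" not in {site.canonical} | set(site.alternates) else "P"
    return "".join(seq)


@pytest.mark.parametrize("cls", ["GGDEF", "EAL", "HD-GYP"])
@pytest.mark.parametrize("k,expect_active", [(0, True), (1, True), (2, False)])
def test_substitution_rule_boundaries(panel, cls, k, expect_active):
    """At most one broken catalytic site is tolerated; two are not."""
    model = panel.catalytic[cls]
    seq = _mutate(model, model.site_positions[:k])
    v = score_site_conservation(seq, model)
    assert v.conserved_count == v.total_sites - k
    assert v.active is expect_active


def test_hd_gyp_alternate_residues_count_as_conserved(panel):
    model = panel.catalytic["HD-GYP"]
    seq = list(model.reference_sequence)
    seq[238 - 1] = "H"  # accepted alternate at position 238
    v = score_site_conservation("".join(seq), model)
    assert v.conserved_count == v.total_sites


def test_site_aligned_to_gap_is_not_conserved(panel):
    model = panel.catalytic["GGDEF"]
    pos = model.site_positions[0]
    seq = model.reference_sequence
    deleted = seq[: pos - 3] + seq[pos + 2 :]  # remove a window covering the site
    v = score_site_conservation(deleted, model)
    assert v.conserved_count <= v.total_sites - 1
    detail = {d.reference_position: d for d in v.site_details}
    assert detail[pos].observed is None and not detail[pos].conserved


def test_short_domain_is_an_error(panel):
    with pytest.raises(ValueError, match="too short"):
        score_site_conservation("MKVLDARND", panel.catalytic["GGDEF"])


def test_zero_site_model_is_an_error():
    model = ReferenceDomainModel(
        domain_class="GGDEF", reference_name="toy",
        reference_sequence="A" * 30, catalytic_sites=(),
    )
    with pytest.raises(ValueError, match="no sites"):
        score_site_conservation("A" * 30, model)


def test_threshold_equal_to_site_count_accepts_everything(panel):
    model = panel.catalytic["GGDEF"]
    seq = _mutate(model, model.site_positions)
    v = score_site_conservation(seq, model, max_substitutions=model.total_sites)
    assert v.conserved_count == 0 and v.active


def test_monotone_degradation_under_added_site_mutations(panel):
    """Each extra broken catalytic site can only lower the conserved count,
    and a domain called inactive never becomes active again."""
    rng = np.random.default_rng(5)
    for model in panel.catalytic.values():
        order = list(rng.permutation(model.site_positions))
        previous = model.total_sites
        was_inactive = False
        for k in range(len(order) + 1):
            v = score_site_conservation(_mutate(model, order[:k]), model)
            assert v.conserved_count <= previous
            if was_inactive:
                assert not v.active
            was_inactive = was_inactive or not v.active
            previous = v.conserved_count


def _verdict(pid, cls, active):
    return ActivityVerdict(
        protein_id=pid, domain_class=cls, reference_name="ref",
        conserved_count=7 if active else 5, total_sites=7, site_details=(),
        active=active, max_substitutions=1,
    )


@pytest.mark.parametrize(
    "domains,category",
    [
        ([("GGDEF", True)], "DGC"),
        ([("GGDEF", False)], "degenerate"),
        ([("EAL", True)], "PDE"),
        ([("HD-GYP", True)], "PDE"),
        ([("HD-GYP", False)], "degenerate"),
        ([("GGDEF", True), ("EAL", True)], "hybrid-bifunctional"),
        ([("GGDEF", True), ("EAL", False)], "hybrid-DGC-only"),
        ([("GGDEF", False), ("EAL", True)], "hybrid-PDE-only"),
        ([("GGDEF", False), ("EAL", False)], "degenerate"),
    ],
)
def test_classify_protein_categories(domains, category):
    verdicts = [_verdict("p", cls, active) for cls, active in domains]
    assert classify_protein(verdicts).category == category


def test_classify_protein_rejects_mixed_ids():
    with pytest.raises(ValueError, match="mix"):
        classify_protein([_verdict("a", "GGDEF", True), _verdict("b", "EAL", True)])


def test_classify_protein_requires_a_verdict():
    with pytest.raises(ValueError):
        classify_protein([])


def test_inventory_matches_generator_ground_truth(panel):
    spec = SyntheticSpec(seed=3, n_active_dgc=5, n_degenerate_dgc=2,
                         n_active_pde=0, n_degenerate_pde=0,
                         n_hybrid_bifunctional=0, n_degenerate_hybrid=0,
                         n_pilz_binder=0, n_pilz_nonbinder=0)
    records, annotations, labels = make_synthetic_proteome(spec, panel)
    _, classifications = classify_proteome(records, annotations, panel)
    counts = inventory(classifications)
    assert counts["DGC"] == 5
    assert counts["degenerate"] == 2
    assert counts["total_active"] == 5


def test_inventory_empty_input():
    assert inventory([])["total_proteins"] == 0


def test_classify_proteome_recovers_every_label(panel):
    """Full synthetic recovery: category per protein matches construction."""
    spec = SyntheticSpec(seed=11)
    records, annotations, labels = make_synthetic_proteome(spec, panel)
    _, classifications = classify_proteome(records, annotations, panel)
    got = {c.protein_id: c.category for c in classifications}
    for label in labels:
        assert got[label.protein_id] == EXPECTED_CATEGORY[label.category]


def test_variant_conserved_count_matches_construction(panel):
    rng = np.random.default_rng(9)
    model = panel.catalytic["EAL"]
    seq, mutated = make_domain_variant(model, 3, rng=rng)
    v = score_site_conservation(seq, model)
    assert len(mutated) == 3
    assert v.conserved_count == v.total_sites - 3
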