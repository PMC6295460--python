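import numpy as np
import pytest

from eetsurvey.align import AlignParams, estimate_evalue, global_align
from eetsurvey.homolog_survey import (
    build_architecture,
    classify_family,
    default_family_rules,
    iterative_search,
)
from eetsurvey.seqio import ProteinRecord, UsageError
from eetsurvey.synthetic_data import (
    SyntheticConfig,
    default_seed_templates,
    generate_proteome,
    seed_template_records,
)

HYDROPHILIC_SAFE = "DENQKST"  # cannot seed motifs (no C/H/A) or helices


class TestBuildArchitecture:
    def test_cyma_template_layout(self, seed_templates):
        profile = build_architecture(seed_templates["CYMA"][0])
        assert profile.n_tm == 1
        assert profile.n_typical == 4
        assert profile.hemes_before_first_tm == 0
        assert profile.hemes_after_last_tm == 4
        assert profile.first_tm_start <= 40

    def test_motif_free_protein_all_zero(self):
        rng = np.random.default_rng(44)
        seq = "".join(rng.choice(list(HYDROPHILIC_SAFE), size=200))
        profile = build_architecture(ProteinRecord(id="r", sequence=seq))
        assert (profile.n_typical, profile.n_atypical, profile.n_tm) == (0, 0, 0)
        assert profile.first_tm_start is None

    def test_cbcl_member_hemes_all_before_tm_block(self, benchmark):
        _cfg, records, manifest = benchmark
        planted = manifest.set_index("id")
        for rec in records:
            if not rec.id.startswith("CBCL"):
                continue
            profile = build_architecture(rec)
            n_planted = len(planted.loc[rec.id, "planted_motifs"].split(";"))
            assert profile.n_typical == n_planted
            assert profile.hemes_before_first_tm == profile.total_hemes

    def test_imch_member_has_atypical_and_tm_first(self, benchmark):
        _cfg, records, _man = benchmark
        rec = next(r for r in records if r.id.startswith("IMCH"))
        profile = build_architecture(rec)
        assert profile.n_atypical == 1
        assert profile.n_typical == 6
        assert profile.hemes_after_last_tm == profile.total_hemes


class TestClassify:
    def test_family_member_assigned(self, benchmark, seed_templates):
        _cfg, records, _man = benchmark
        member = next(r for r in records if r.id.startswith("CYMA"))
        profile = build_architecture(member)
        a = classify_family(profile, member, seed_templates)
        assert a is not None and a.family == "CYMA"
        assert a.evalue <= 0.01
        assert all(a.rules_satisfied.values())
        assert a.pct_identity > 55

    def test_similar_but_heme_free_rejected(self, benchmark, seed_templates):
        """A template-related protein whose heme motifs were deleted passes the
        similarity gate but fails verification."""
        _cfg, records, _man = benchmark
        decoy = next(r for r in records if r.id.startswith("DEC_B"))
        profile = build_architecture(decoy)
        assert classify_family(profile, decoy, seed_templates) is None

    def test_unrelated_motif_bearing_rejected(self, benchmark, seed_templates):
        _cfg, records, _man = benchmark
        decoy = next(r for r in records if r.id.startswith("DEC_M"))
        profile = build_architecture(decoy)
        assert classify_family(profile, decoy, seed_templates) is None

    def test_empty_templates_rejected(self, benchmark):
        _cfg, records, _man = benchmark
        rec = records[0]
        with pytest.raises(UsageError):
            classify_family(build_architecture(rec), rec, {"CYMA": []})


class TestIterativeSearch:
    def test_seed_self_recovery(self, seed_templates):
        """Searching the seed templates against themselves assigns every
        template to its own family in round 1 at 100% identity."""
        database = [t for fam in seed_templates.values() for t in fam]
        assignments, _log = iterative_search(database, seed_templates)
        assert len(assignments) == len(database)
        for a in assignments:
            assert a.iteration == 1
            assert a.pct_identity == 100.0
            assert a.protein_id.split("_", 1)[1].startswith(a.family)

    def test_max_rounds_validation(self, seed_templates):
        db = [seed_templates["CYMA"][0]]
        with pytest.raises(UsageError):
            iterative_search(db, seed_templates, max_rounds=0)

    def test_two_round_chain_discovery(self):
        """B is discoverable from seed A; C is similar only to B, so C's
        E-value against A alone is insignificant and C surfaces in round 2.

        Uses stiff (BLAST-like) gap penalties: with the survey's default
        near-free gap extension, global alignment can re-register the
        conserved TM/motif elements through long cheap gaps, so even an
        otherwise unrelated family member scores significantly against any
        template and a multi-round chain cannot be constructed."""
        rng = np.random.default_rng(55)
        template, layout = default_seed_templates()["CYMA"][0]
        n = len(template.sequence)
        mask = layout.mask(n)
        bg = [i for i in range(n) if not mask[i]]

        def mutate(seq, positions, avoid):
            out = list(seq)
            for i in positions:
                c = avoid[i]
                while c == avoid[i]:
                    c = HYDROPHILIC_SAFE[rng.integers(len(HYDROPHILIC_SAFE))]
                out[i] = c
            return "".join(out)

        def mutate_dissimilar(seq, positions, avoid):
            # replacement maximally dissimilar to the template residue, so
            # C scores like an unrelated sequence against A
            from eetsurvey.align import load_matrix

            mat = load_matrix("BLOSUM62")
            out = list(seq)
            for i in positions:
                out[i] = min((x for x in HYDROPHILIC_SAFE if x != avoid[i]),
                             key=lambda x: mat[avoid[i], x])
            return "".join(out)

        b_seq = mutate(template.sequence, rng.choice(bg, size=75, replace=False),
                       template.sequence)
        c_seq = mutate_dissimilar(b_seq, [i for i in bg if b_seq[i] == template.sequence[i]],
                                  template.sequence)
        b = ProteinRecord(id="chain_B", sequence=b_seq)
        c = ProteinRecord(id="chain_C", sequence=c_seq)

        from eetsurvey.synthetic_data import _decoy_random

        filler = [_decoy_random(np.random.default_rng(1000 + i), f"fill_{i:03d}",
                                lo=400, hi=400)[0] for i in range(150)]
        database = [b, c] + filler
        db_n = sum(len(p) for p in database)

        # verify the E-value premises before the search behavior
        params = AlignParams(gap_open=15, gap_extend=8)
        e_ba = estimate_evalue(global_align(b, template, params).score, len(b), db_n, params)
        e_ca = estimate_evalue(global_align(c, template, params).score, len(c), db_n, params)
        e_cb = estimate_evalue(global_align(c, b, params).score, len(c), db_n, params)
        assert e_ba < 0.01 and e_cb < 0.01
        assert e_ca > 0.01

        seeds = {"CYMA": [template], "CBCL_MTRH_MTOC": [], "IMCH": []}
        assignments, _log = iterative_search(database, seeds, params=params)
        by_id = {a.protein_id: a for a in assignments}
        assert set(by_id) == {"chain_B", "chain_C"}
        assert by_id["chain_B"].iteration == 1
        assert by_id["chain_C"].iteration == 2
        assert by_id["chain_C"].best_template_id == "chain_B"

    def test_no_dual_assignment_and_gates_hold(self, benchmark_search):
        _records, _manifest, assignments, _log = benchmark_search
        ids = [a.protein_id for a in assignments]
        assert len(ids) == len(set(ids))
        for a in assignments:
            assert a.evalue <= 0.01
            assert all(a.rules_satisfied.values())

    def test_idempotent_when_seeded_with_output(self, seed_templates):
        config = SyntheticConfig(seed=7, n_per_family={"CYMA": 3, "CBCL_MTRH_MTOC": 3, "IMCH": 3},
                                 n_decoys=12)
        records, _man = generate_proteome(config)
        first, _ = iterative_search(records, seed_templates)
        by_id = {r.id: r for r in records}
        enriched = {fam: list(ts) for fam, ts in seed_template_records().items()}
        for a in first:
            enriched[a.family].append(by_id[a.protein_id])
        second, _ = iterative_search(records, enriched)
        assert {(a.protein_id, a.family) for a in first} == \
               {(a.protein_id, a.family) for a in second}


class TestRules:
    def test_rules_are_config_overridable(self, benchmark):
        _cfg, records, _man = benchmark
        rules = default_family_rules()
        rules["CYMA"].total_hemes = (99, 99)  # impossible bound
        member = next(r for r in records if r.id.startswith("CYMA"))
        profile = build_architecture(member)
        assert not all(rules["CYMA"].evaluate(profile).values())
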