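import numpy as np
import pytest

from conftest import brute_force_matches, mask_rows_for
from fragpick.errors import DataError, InvalidRegexError, UsageError
from fragpick.fixtures import make_decoy_pool
from fragpick.fragment_store import database_from_fragments
from fragpick.index import build_index, select_references
from fragpick.query_engine import (
    Match,
    StructuralQuery,
    apply_limit,
    query,
    query_auto_widen,
    query_masked,
)


def as_pairs(matches):
    return [(m.fragment_id, m.rmsd) for m in matches]


def assert_equals_oracle(matches, oracle, tol=1e-9):
    assert [m.fragment_id for m in matches] == [fid for fid, _ in oracle]
    for m, (_, r) in zip(matches, oracle):
        assert m.rmsd == pytest.approx(r, abs=tol)


class TestSelfMatch:
    def test_database_fragment_at_zero_threshold(self, decoy_db, decoy_index):
        frag = decoy_db.fragments[17]
        sq = StructuralQuery(query_fragment=frag, threshold=0.0)
        matches = query(decoy_db, decoy_index, sq)
        assert matches[0].fragment_id == 17
        assert matches[0].rmsd == pytest.approx(0.0, abs=1e-9)


class TestOracleEquivalence:
    def test_huge_threshold_returns_everything_sorted(self, decoy_db, decoy_index):
        frag = decoy_db.fragments[0]
        sq = StructuralQuery(query_fragment=frag, threshold=1e6)
        matches = query(decoy_db, decoy_index, sq)
        assert len(matches) == len(decoy_db)
        rmsds = [m.rmsd for m in matches]
        assert rmsds == sorted(rmsds)

    @pytest.mark.parametrize("case", range(10))
    def test_random_queries_match_brute_force(self, decoy_db, decoy_index, case):
        rng = np.random.default_rng(100 + case)
        base = decoy_db.coords_matrix[rng.integers(len(decoy_db))]
        q = base + rng.normal(scale=0.5, size=base.shape)
        d_q = rng.uniform(0.2, 4.0)
        sq = StructuralQuery(query_fragment=q, threshold=d_q)
        matches = query(decoy_db, decoy_index, sq)
        oracle = brute_force_matches(decoy_db, q, d_q)
        assert_equals_oracle(matches, oracle)

    def test_with_filters_matches_brute_force(self, decoy_db, decoy_index):
        rng = np.random.default_rng(200)
        q = decoy_db.coords_matrix[5] + rng.normal(
            scale=0.8, size=decoy_db.coords_matrix[5].shape
        )
        excluded = frozenset(
            f.pdb_code for f in decoy_db.fragments[::7]
        )
        # pattern derived from one sequence with wildcards: anchored match
        seq = decoy_db.fragments[10].sequence
        pattern = seq[0] + "." * (len(seq) - 2) + seq[-1]
        sq = StructuralQuery(
            query_fragment=q,
            threshold=5.0,
            sequence_constraint=pattern,
            excluded_pdb_codes=excluded,
        )
        matches = query(decoy_db, decoy_index, sq)
        oracle = brute_force_matches(
            decoy_db, q, 5.0, excluded=excluded, regex=pattern
        )
        assert_equals_oracle(matches, oracle)
        assert all(m.pdb_code not in excluded for m in matches)

    def test_regex_is_anchored(self, decoy_db, decoy_index):
        seq = decoy_db.fragments[3].sequence
        sq = StructuralQuery(
            query_fragment=decoy_db.fragments[3],
            threshold=1e6,
            sequence_constraint=seq[1:3],  # substring: must NOT match anywhere
        )
        matches = query(decoy_db, decoy_index, sq)
        assert all(
            decoy_db.fragments[m.fragment_id].sequence == seq[1:3] for m in matches
        )

    def test_invalid_regex_names_pattern(self, decoy_db, decoy_index):
        sq = StructuralQuery(
            query_fragment=decoy_db.fragments[0],
            threshold=1.0,
            sequence_constraint="[unclosed",
        )
        with pytest.raises(InvalidRegexError, match=r"\[unclosed"):
            query(decoy_db, decoy_index, sq)

    def test_monotone_in_threshold(self, decoy_db, decoy_index):
        frag = decoy_db.fragments[8]
        prev = set()
        for d_q in (0.5, 1.5, 3.0, 6.0):
            sq = StructuralQuery(query_fragment=frag, threshold=d_q)
            got = {m.fragment_id for m in query(decoy_db, decoy_index, sq)}
            assert prev <= got
            prev = got

    def test_filter_commutativity(self, decoy_db, decoy_index):
        """Same final set whether exclusion is done by the engine or by
        post-filtering a regex-only result (and vice versa)."""
        q = decoy_db.fragments[2]
        excluded = frozenset(f.pdb_code for f in decoy_db.fragments[::11])
        pattern = ".*"
        both = query(
            decoy_db,
            decoy_index,
            StructuralQuery(
                query_fragment=q,
                threshold=4.0,
                sequence_constraint=pattern,
                excluded_pdb_codes=excluded,
            ),
        )
        regex_only = query(
            decoy_db,
            decoy_index,
            StructuralQuery(
                query_fragment=q, threshold=4.0, sequence_constraint=pattern
            ),
        )
        manual = [m for m in regex_only if m.pdb_code not in excluded]
        assert as_pairs(both) == as_pairs(manual)

    def test_length_mismatch_errors(self, decoy_db, decoy_index):
        q = np.zeros((4 * (decoy_db.fragment_length + 1), 3))
        with pytest.raises(DataError):
            query(decoy_db, decoy_index, StructuralQuery(query_fragment=q))

    def test_pruning_reduces_candidates(self, decoy_db, decoy_index):
        # statistical sanity: a tight query should not refine everything
        from fragpick.index import STORAGE_EPSILON, range_candidates
        from fragpick.geometry import qcp_rmsd

        q = decoy_db.fragments[4].coords
        d_q = 0.3
        cand = None
        for j in range(decoy_index.n_references):
            d = qcp_rmsd(q, decoy_index.reference_coords[j])
            ids = range_candidates(
                decoy_index,
                j,
                max(0.0, d - d_q) - STORAGE_EPSILON,
                d + d_q + STORAGE_EPSILON,
            )
            cand = np.sort(ids) if cand is None else np.intersect1d(cand, ids)
        assert len(cand) < len(decoy_db)


class TestMaskedQuery:
    def test_full_mask_equals_unmasked(self, decoy_db, decoy_index):
        frag = decoy_db.fragments[6]
        full = frozenset(range(decoy_db.fragment_length))
        masked = query_masked(
            decoy_db,
            StructuralQuery(query_fragment=frag, threshold=2.0, mask=full),
        )
        plain = query(
            decoy_db, decoy_index, StructuralQuery(query_fragment=frag, threshold=2.0)
        )
        assert as_pairs(masked) == pytest.approx(as_pairs(plain))

    def test_anchor_mask_finds_planted_fragment(self, base_fragment):
        """A fragment sharing the query's anchors but a different middle
        must come back at RMSD 0 under an anchor-only mask."""
        L = base_fragment.length
        rng = np.random.default_rng(33)
        planted_coords = base_fragment.coords.reshape(L, 4, 3).copy()
        for p in range(3, L - 3):
            planted_coords[p] += rng.normal(scale=2.0, size=(4, 3))
        from fragpick.fragment_store import BackboneResidue, Fragment

        residues = [
            BackboneResidue(
                base_fragment.residues[j].amino_acid,
                planted_coords[j],
                ("A", j + 1, " "),
            )
            for j in range(L)
        ]
        planted = Fragment(0, "PLNT", "A", residues)
        noise = make_decoy_pool(base_fragment, 40, 1.0, seed=34)
        db = database_from_fragments([planted] + list(noise))
        mask = frozenset([0, 1, 2, L - 3, L - 2, L - 1])
        sq = StructuralQuery(query_fragment=base_fragment, threshold=0.5, mask=mask)
        matches = query_masked(db, sq)
        assert matches[0].fragment_id == 0
        assert matches[0].rmsd == pytest.approx(0.0, abs=1e-9)
        oracle = brute_force_matches(
            db, base_fragment.coords, 0.5, mask_rows=mask_rows_for(mask, L)
        )
        assert_equals_oracle(matches, oracle)

    def test_masked_matches_oracle_with_filters(self, decoy_db):
        rng = np.random.default_rng(35)
        L = decoy_db.fragment_length
        mask = frozenset([0, 2, 5, L - 1])
        q = decoy_db.coords_matrix[9] + rng.normal(
            scale=0.4, size=decoy_db.coords_matrix[9].shape
        )
        excluded = frozenset(f.pdb_code for f in decoy_db.fragments[:50:5])
        sq = StructuralQuery(
            query_fragment=q, threshold=2.0, mask=mask, excluded_pdb_codes=excluded
        )
        matches = query_masked(decoy_db, sq)
        oracle = brute_force_matches(
            decoy_db,
            q,
            2.0,
            mask_rows=mask_rows_for(mask, L),
            excluded=excluded,
            use_kabsch=True,
        )
        assert [m.fragment_id for m in matches] == [fid for fid, _ in oracle]
        for m, (_, r) in zip(matches, oracle):
            assert m.rmsd == pytest.approx(r, abs=1e-6)

    def test_mask_too_small(self, decoy_db):
        with pytest.raises(UsageError):
            StructuralQuery(
                query_fragment=decoy_db.fragments[0],
                threshold=1.0,
                mask=frozenset([0, 1]),
            )


class TestLimits:
    def make_matches(self, n):
        return [
            Match(fragment_id=i, pdb_code="XXXX", chain="A",
                  start_residue=(1, " "), rmsd=r)
            for i, r in [(3, 0.1), (0, 0.2), (7, 0.3), (1, 0.4), (5, 0.5)][:n]
        ]

    def test_n_larger_than_list(self):
        m = self.make_matches(5)
        assert apply_limit(m, "best", 10) == m

    def test_best_one_is_global_minimum(self):
        m = self.make_matches(5)
        assert apply_limit(m, "best", 1)[0].fragment_id == 3

    def test_first_is_scan_order_then_sorted(self):
        m = self.make_matches(5)
        out = apply_limit(m, "first", 3)
        # lowest three fragment ids are 0, 1, 3; output re-sorted by rmsd
        assert [x.fragment_id for x in out] == [3, 0, 1]

    def test_query_first_limit_equals_apply_limit(self, decoy_db, decoy_index):
        frag = decoy_db.fragments[12]
        full = query(
            decoy_db, decoy_index, StructuralQuery(query_fragment=frag, threshold=3.0)
        )
        limited = query(
            decoy_db,
            decoy_index,
            StructuralQuery(query_fragment=frag, threshold=3.0, limit=("first", 5)),
        )
        assert as_pairs(limited) == as_pairs(apply_limit(full, "first", 5))

    def test_query_best_limit(self, decoy_db, decoy_index):
        frag = decoy_db.fragments[12]
        full = query(
            decoy_db, decoy_index, StructuralQuery(query_fragment=frag, threshold=3.0)
        )
        limited = query(
            decoy_db,
            decoy_index,
            StructuralQuery(query_fragment=frag, threshold=3.0, limit=("best", 4)),
        )
        assert as_pairs(limited) == as_pairs(full[:4])

    def test_bad_mode(self):
        with pytest.raises(UsageError):
            apply_limit([], "worst", 1)


class TestAutoWiden:
    def test_target_met_immediately(self, decoy_db, decoy_index):
        frag = decoy_db.fragments[0]
        sq = StructuralQuery(
            query_fragment=frag, threshold=5.0, auto_widen=(1, 0.25, 10.0)
        )
        res = query_auto_widen(decoy_db, decoy_index, sq)
        assert res.threshold == 5.0
        assert not res.under_target
        assert len(res.matches) >= 1

    def test_under_target_flag(self, decoy_db, decoy_index):
        frag = decoy_db.fragments[0]
        sq = StructuralQuery(
            query_fragment=frag,
            threshold=0.1,
            auto_widen=(len(decoy_db) + 1, 0.5, 2.0),
        )
        res = query_auto_widen(decoy_db, decoy_index, sq)
        assert res.under_target
        assert len(res.matches) < len(decoy_db) + 1

    def test_final_equals_fresh_query(self, decoy_db, decoy_index):
        frag = decoy_db.fragments[20]
        sq = StructuralQuery(
            query_fragment=frag, threshold=0.05, auto_widen=(10, 0.3, 10.0)
        )
        res = query_auto_widen(decoy_db, decoy_index, sq)
        fresh = query(
            decoy_db,
            decoy_index,
            StructuralQuery(query_fragment=frag, threshold=res.threshold),
        )
        assert as_pairs(res.matches) == as_pairs(fresh)
        assert len(res.matches) >= 10

    def test_bad_parameters(self, decoy_db, decoy_index):
        frag = decoy_db.fragments[0]
        with pytest.raises(UsageError):
            query_auto_widen(
                decoy_db,
                decoy_index,
                StructuralQuery(
                    query_fragment=frag, threshold=1.0, auto_widen=(5, -0.1, 10.0)
                ),
            )
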