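# fragpick

A protein fragment picker. Build a database of fixed-length backbone
fragments (N, CA, C, O per residue) from any set of PDB files, then query
it with a fragment and an RMSD threshold. Because superposition RMSD is a
metric, precomputed distances to a few *reference* fragments let the engine
discard almost all of the database with triangle-inequality bounds before
any query-time RMSD is computed; an exact refinement pass then guarantees
the result is identical to a brute-force scan. Also included: sequence
regular-expression constraints, gapped (masked) queries for loop grafting,
automatic threshold widening, a one-versus-many RMSD ranker, and a
deterministic synthetic-structure generator used by the test suite.

RMSDs come from a vectorised quaternion characteristic polynomial (QCP)
kernel; an independent Kabsch/SVD implementation exists purely as a
cross-validation oracle.

## CLI

```sh
# 1. build a database of 9-residue fragments from a list of PDB paths
fragpick makedb --pdb-list paths.txt --length 9 --out db.bin

# 2. build the reference-fragment RMSD index (3 refs, far-apart heuristic)
fragpick index --db db.bin --seed 1 --out db.idx

# 3. query with a fragment and a threshold
fragpick query --db db.bin --idx db.idx --query q.pdb --rmsd 1.0 \
    --seq-regex 'A.{7}G' --exclude-pdbs skip.txt --best 50 --out matches.tsv

# gapped query: rank on the first/last three residues only
# (bypasses the index — masked RMSD is a different metric — and scans linearly)
fragpick query --db db.bin --query q.pdb --mask 1-3,7-9 --rmsd 0.8

# widen the threshold until 100 matches are found
fragpick query --db db.bin --idx db.idx --query q.pdb --rmsd 0.2 \
    --auto-widen 100,0.25,10

# one-versus-many ranking, no database/index needed
fragpick rank --query q.pdb --pool-dir fragments/ --out ranked.tsv
fragpick rank --query q.pdb --db db.bin --out ranked.tsv   # much faster

# extract fragments back out as PDB files
fragpick extract --db db.bin --random 10 --seed 3 --out-dir out/

# synthetic fixtures (helices, broken chains, decoy pools)
fragpick fixtures --kind decoys --n 100 --length 9 --sigma 0.5 --out fx/
```

Query output is TSV: `rank, fragment_id, pdb_code, chain, start_residue,
rmsd`. Sequence regexes are anchored (they must describe the entire
fragment sequence). Exit codes: 0 success, 1 usage error, 2 data error.
All results are deterministic given the seeds and invariant to `--threads`.

## Library

```python
from fragpick import (extract_fragments, parse_pdb_file, select_references,
                      build_index, StructuralQuery, query)

db = extract_fragments([parse_pdb_file(p) for p in paths], length=9)
idx = build_index(db, select_references(db, seed=1))
matches = query(db, idx, StructuralQuery(query_fragment=db.fragments[0],
                                         threshold=1.0))
```

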