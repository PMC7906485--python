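"""Recover planted biclusters from a small simulated loading matrix.

Builds the 40-subject x 10-feature fixture with three disjoint planted
blocks (13 subjects x 3 features each), runs the exhaustive permutation
search, and compares the stable biclusters with the planted truth.
"""

from nbic import SearchConfig, recovery_report, run_nbic, simulation2_fixture

matrix, truth = simulation2_fixture(seed=1)
print(f"loading matrix: {matrix.n_subjects} subjects x {matrix.n_features} features")
print(f"planted blocks: {len(truth)}")

config = SearchConfig(N=11, K=3, O=35, M=4, permutation_budget=200, seed=1)
biclusters = run_nbic(matrix, config)

print(f"\nstable biclusters found: {len(biclusters)}")
for i, b in enumerate(biclusters, 1):
    print(
        f"  BiC {i}: {b.n_subjects} subjects x features {sorted(b.feature_set)}"
        f" (rediscovered in {b.frequency} of 200 permutation orders)"
    )

# best-match F1 per planted block: 1.0 means the block was recovered exactly
print("\nrecovery against the planted truth (F1 over matrix cells):")
print(recovery_report(biclusters, truth).to_string(index=False))
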