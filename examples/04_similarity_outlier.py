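"""MEMO vectorization and the outlier ensemble on a planted outlier.

Ten synthetic extracts: nine share an MS2 fragment vocabulary, the tenth
draws from a disjoint one.  The word-count fingerprints are blank-filtered,
turned into a Bray-Curtis dissimilarity matrix and mined by LOF, a
one-class SVM and an Isolation Forest; SC = 1 if any detector votes outlier.
"""

from extractrank import (
    FixtureSpec,
    detect_outliers,
    distance_matrix,
    generate_bundle,
    memo_vectorize,
    remove_blank_words,
)
from extractrank.io_tables import blank_extracts, sample_extracts

bundle = generate_bundle(FixtureSpec(n_extracts=10, planted_outlier=9, seed=42))
scored = sample_extracts(bundle.metadata)
blanks = blank_extracts(bundle.metadata)

memo = memo_vectorize(bundle.spectra, bundle.extract_assignment, extracts=scored + blanks)
print(f"MEMO matrix: {memo.shape[0]} extracts x {memo.shape[1]} words")
memo = remove_blank_words(memo, blanks)
print(f"after blank-word removal: {memo.shape[0]} x {memo.shape[1]}")

dist = distance_matrix(memo, metric="braycurtis")
print(f"\nmean distance of sample_09 to the rest: {dist.loc['sample_09'].drop('sample_09').mean():.3f}")
print(f"mean distance among the other nine:     {dist.drop('sample_09').drop(columns='sample_09').to_numpy().mean():.3f}")

verdict = detect_outliers(dist, seed=42)
print("\ndetector votes and SC:")
print(verdict.flags.assign(SC=verdict.sc).to_string())
print("\nsample_09's disjoint vocabulary makes it the ensemble outlier -> SC = 1.")
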