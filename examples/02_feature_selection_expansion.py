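"""Chi-square feature selection and synonym expansion, step by step.

For each class, the k tokens with the highest one-vs-rest chi-square score
(among tokens associated with that class) are selected; any document token
whose embedding is cosine-similar (>= t) to a selected feature then
increments that feature's count — conceptually adding the feature to the
document even when only a synonym is present.
"""

import numpy as np

from bowexp import (
    Corpus,
    Document,
    EmbeddingTable,
    FeatureSelectionConfig,
    expand_counts,
    select_features,
)

corpus = Corpus(tuple([
    Document("p1", ("cough", "fever", "tired"), "flu"),
    Document("p2", ("cough", "fever"), "flu"),
    Document("p3", ("fever", "cough", "rest"), "flu"),
    Document("p4", ("itch", "red", "tired"), "rash"),
    Document("p5", ("itch", "red"), "rash"),
    Document("p6", ("red", "itch", "rest"), "rash"),
]))

selected = select_features(corpus, FeatureSelectionConfig(k=2, t=0.9))
print("selected features (class, feature, chi-square):")
for w in selected.features:
    print(f"  {selected.class_of[w]:>5}  {w:>6}  {selected.score_of[w]:.2f}")

# 'hacking' is a synonym of 'cough' in this toy embedding space (cos ~ 0.95)
c = 0.95
emb = EmbeddingTable({
    "cough": np.array([1.0, 0.0]),
    "hacking": np.array([c, np.sqrt(1 - c * c)]),
    "itch": np.array([0.0, 1.0]),
})
doc = Document("new", ("hacking", "unrelated"), "flu")
out = expand_counts(doc, {"hacking": 1.0, "unrelated": 1.0}, selected, emb, t=0.9)
print("expanded counts for a document that says 'hacking', not 'cough':", out)
# The selected feature 'cough' gains a count although the document never
# contains it — this is what lets a linear model recognize unseen synonyms.
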