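"""Generate a long-tailed synthetic corpus and inspect its class structure.

The generator emulates patient-description classification data: a Zipf-shaped
class-frequency law with some classes as rare as 2 in 10,000 documents, short
documents, class-indicative signature tokens grouped into synonym clusters,
and shared background vocabulary.
"""

from bowexp import class_prevalence, generate_corpus, long_tail_config, rare_subset

config = long_tail_config(seed=0)
corpus = generate_corpus(config)
prev = class_prevalence(corpus)

print(f"documents: {len(corpus)}   classes: {len(corpus.classes)}")
print(f"largest class prevalence:  {max(prev.values()):.4f}")
print(f"smallest class prevalence: {min(prev.values()):.4f}")
rare = rare_subset(corpus, threshold=0.0002)
print(f"rare classes (prevalence <= 0.02%): {len(rare)}")
print("example document:", " ".join(corpus.documents[0].tokens[:8]), "...")

# The rare count is what the rare-scope learning curves average over: with a
# 10,000-document corpus, each rare class has exactly 2 documents, i.e. one
# training document per class at the 10% training proportion after an 80/20
# split.
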