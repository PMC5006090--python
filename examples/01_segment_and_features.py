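"""Segment a small Results passage into clauses and inspect their features.

Builds one document in memory, detects figure references and citations,
splits it into clause-level discourse units, and prints the sparse feature
vector of each clause.  The feature families are pos:* (part-of-speech tag
counts), lex:* (verbs/adverbs), link:* (figure/citation flags) and cue:*
(lexicon phrase hits); these are the inputs of the discourse labelers.
"""

from scidisc import Document, Section, annotate, extract_features, segment_document

TEXT = (
    "RESULTS\n\n"
    "RAF1 binds MEK1 in many cell types [12]. To address this question, "
    "we examined the role of RAF1 in ERK2 signaling. Cells were transfected "
    "with RAF1 and lysates were blotted for MEK1. Binding of RAF1 to MEK1 "
    "increased markedly (Fig. 2B), suggesting a direct interaction."
)

document = annotate(Document("demo", TEXT, [Section("results", 0, len(TEXT))]))
print(f"{len(document.figure_refs)} figure reference(s), "
      f"{len(document.citations)} citation(s)\n")

for clause in segment_document(document):
    vector = extract_features(clause, document)
    kind = "heading" if clause.is_heading else "clause"
    print(f"[{kind}] {clause.text}")
    names = sorted(vector.features)
    print("   features:", ", ".join(names), "\n")

# The last clause pair shows the unit the labelers see: the result-bearing
# clause carries link:figure, the implication-bearing one lex:suggesting.
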