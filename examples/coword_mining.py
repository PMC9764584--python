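"""Mine high-frequency terms and their co-word structure from policy texts.

Before an evaluation schema is fixed, a co-word analysis of the corpus shows
which concepts dominate and which travel together — the empirical basis for
choosing evaluation dimensions.
"""

import pmcindex as pmc
from pmcindex.textmine import TokenizedCorpus

docs = {
    "d1": "Health education and health service management in every county.",
    "d2": "Promote health culture; health education enters schools.",
    "d3": "Service management for community health promotion.",
}
corpus = TokenizedCorpus.from_texts(docs, stopwords=("and", "in", "for", "every"))

freqs = pmc.term_frequencies(corpus, top_k=5)
print("top terms:", ", ".join(f"{t}:{n}" for t, n in freqs))

mat = pmc.coword_matrix(corpus, [t for t, _ in freqs])
print("co-word matrix (documents sharing both terms):")
print(mat.to_frame())
# The diagonal counts documents containing each term; off-diagonals show which
# concept pairs co-occur, e.g. "health" with "education" versus "management".
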