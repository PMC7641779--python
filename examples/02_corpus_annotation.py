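"""Character-offset annotation, BIO conversion and inter-annotator agreement.

Spans are 0-based half-open offsets into one label section; BIO conversion
is exact and reversible, and agreement is the exact-match F score
2·|matches| / (|a|+|b|).
"""

from pgxkit.corpus import SpanAnnotation, agreement_f, bio_to_spans, spans_to_bio, tokenize

text = "2 mg orally once daily"
seq = tokenize(text)
spans = [
    SpanAnnotation(0, 0, 4, "Daily_Dose"),     # "2 mg"
    SpanAnnotation(0, 12, 22, "Frequency"),    # "once daily"
]
tags = spans_to_bio(seq, spans)
print(list(seq.tokens))
print(tags)  # B-/I- mark span starts and continuations, O everything else
assert bio_to_spans(seq, tags) == spans  # the conversion is lossless

# a second annotator who missed one of the four spans below agrees at F = 2*3/(4+3) = 0.857
a = spans + [SpanAnnotation(1, 0, 5, "Drug"), SpanAnnotation(1, 8, 12, "Gene")]
b = a[:3]
print(f"agreement F = {agreement_f(a, b):.3f}")
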