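"""Normalize free-text relation expressions from a drug-label sentence.

The synonym table maps literal surface expressions (case-insensitive, with
a *** wildcard for e.g. gene variants) to registered relation names.
"""

from pgxkit.normalize import load_default_rules, normalize_expression
from pgxkit.schema import build_default_registry

table = load_default_rules(build_default_registry())
text = ("TRAMETINIB is indicated in combination with dabrafenib for the treatment "
        "of melanoma in patients with BRAF V600E mutation")

for m in normalize_expression(text, table):
    cap = f"  (captures: {m.capture})" if m.capture else ""
    print(f"[{m.start:3d},{m.end:3d}) {m.surface!r} -> {m.normalized}{cap}")
# Each line is one expression found left-to-right: its character span, the
# literal surface matched, and the normalized relation it denotes.
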