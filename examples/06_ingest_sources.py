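"""Parse the three source dialects and lift the records into schema entities.

SPL XML gives sectioned label text; DrugBank-dialect XML gives drug
attributes (with CAS checksum validation); RxNorm RRF lines give dose-form
relations. All fixtures here are synthetic.
"""

from pgxkit.ingest import parse_drugbank, parse_rxnorm_rrf, parse_spl, records_to_entities
from pgxkit.schema import build_default_registry, validate_entity
from pgxkit.synthdata import GeneratorConfig, emit_spl, generate_corpus

registry = build_default_registry()

# SPL: emit a synthetic label and read it back
doc = generate_corpus(GeneratorConfig(n_documents=1, seed=4))[0][0]
parsed = parse_spl(emit_spl(doc))
print(f"SPL {parsed.doc_id}: {len(parsed.sections)} sections, first:",
      parsed.sections[0][1][:60], "...")

drugbank_xml = """<drugbank><drug>
  <name>Trametinib</name>
  <chemical-formula>C26H23FIN5O4</chemical-formula>
  <molecular-weight>615.39</molecular-weight>
  <groups><group>approved</group></groups>
  <cas-number>871700-17-3</cas-number>
  <unii>33E86K87QN</unii>
  <indication>Treatment of metastatic melanoma.</indication>
</drug></drugbank>"""
records = parse_drugbank(drugbank_xml)
print(f"DrugBank: {records[0].name}, {records[0].molecular_weight} Da, "
      f"CAS {records[0].cas} (checksum ok: {records[0].cas_valid})")

conso = ["101|ENG|P|L|PF|S|Y|A||||RXNORM|DF|101|Oral Tablet||N|"]
rel = ["102|A|CUI|RO|101|B|CUI|has_dose_form|R1||RXNORM||||N|"]
concepts, relations = parse_rxnorm_rrf(conso, rel)
print(f"RxNorm: {len(concepts)} concepts, {len(relations)} dose-form relations")

entities = records_to_entities(records, registry, dose_form_concepts=concepts)
print("entities valid:", all(validate_entity(e, registry) == [] for e in entities))
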