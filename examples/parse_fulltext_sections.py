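"""Split a JATS full-text article into typed subsections.

A subsection is any heading plus the prose before the next heading;
ancestor headings (and the article title) are inherited, figure captions
become subsections of type "figure", and a heading with no text of its
own yields no subsection.
"""

from efip import parse_jats

xml = """<?xml version="1.0"?>
<article>
 <front><article-meta>
  <article-id pub-id-type="pmcid">PMC_EX1</article-id>
  <title-group><article-title>Phosphorylation of PLN</article-title></title-group>
 </article-meta>
 <abstract><p>PLN regulates the calcium pump.</p></abstract></front>
 <body>
  <sec sec-type="intro"><title>Introduction</title>
   <p>PLN phosphorylation controls SERCA activity.</p></sec>
  <sec><title>Results</title>
   <sec><title>PP1 association with PLN and effect of PKA</title>
    <p>PP1 associated with PLN. PKA phosphorylates PLN at Ser16.</p>
    <fig><label>Figure 1</label>
     <caption><p>Binding of PP1 to PLN.</p></caption></fig>
   </sec>
  </sec>
  <sec sec-type="materials|methods"><title>GST pull down assay</title>
   <p>Beads were washed three times.</p></sec>
 </body>
</article>"""

doc = parse_jats(xml)
print(f"doc {doc.doc_id}: {len(doc.subsections)} subsections")
for sub in doc.subsections:
    chain = " > ".join(sub.inherited_headings + [sub.heading])
    print(f"  [{sub.section_type:<9}] {chain}  "
          f"({len(sub.sentences)} sentences)")

# The bare "Results" heading has no prose of its own, so it appears only
# as an inherited heading of its child subsection; the figure caption is
# its own subsection of type "figure", and the sec-type attribute maps
# the assay section to "methods".
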