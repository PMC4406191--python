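<?xml version="1.0" encoding="UTF-8"?>
<!-- Nested pathway for recursive interaction counting: Outer contains
     reaction R1 and sub-pathway Inner; Inner contains R2 and R3.
     Counting interactions within Outer therefore yields 3. -->
<rdf:RDF xmlns:rdf="http://www.w3.org/1999/02/22-rdf-syntax-ns#"
         xmlns:owl="http://www.w3.org/2002/07/owl#"
         xmlns:bp="http://www.biopax.org/release/biopax-level3.owl#">
  <owl:Ontology rdf:about="http://biopaxnet.example/nested">
    <owl:imports rdf:resource="http://www.biopax.org/release/biopax-level3.owl"/>
  </owl:Ontology>
  <bp:Pathway rdf:about="http://biopaxnet.example/nested#Outer">
    <bp:displayName>Outer pathway</bp:displayName>
    <bp:pathwayComponent rdf:resource="http://biopaxnet.example/nested#R1"/>
    <bp:pathwayComponent rdf:resource="http://biopaxnet.example/nested#Inner"/>
  </bp:Pathway>
  <bp:Pathway rdf:about="http://biopaxnet.example/nested#Inner">
    <bp:displayName>Inner sub-pathway</bp:displayName>
    <bp:pathwayComponent rdf:resource="http://biopaxnet.example/nested#R2"/>
    <bp:pathwayComponent rdf:resource="http://biopaxnet.example/nested#R3"/>
  </bp:Pathway>
  <bp:Pathway rdf:about="http://biopaxnet.example/nested#Empty">
    <bp:displayName>Pathway with no components</bp:displayName>
  </bp:Pathway>
  <bp:BiochemicalReaction rdf:about="http://biopaxnet.example/nested#R1">
    <bp:left rdf:resource="http://biopaxnet.example/nested#X1"/>
    <bp:right rdf:resource="http://biopaxnet.example/nested#X2"/>
  </bp:BiochemicalReaction>
  <bp:BiochemicalReaction rdf:about="http://biopaxnet.example/nested#R2">
    <bp:left rdf:resource="http://biopaxnet.example/nested#X2"/>
    <bp:right rdf:resource="http://biopaxnet.example/nested#X3"/>
  </bp:BiochemicalReaction>
  <bp:BiochemicalReaction rdf:about="http://biopaxnet.example/nested#R3">
    <bp:left rdf:resource="http://biopaxnet.example/nested#X3"/>
    <bp:right rdf:resource="http://biopaxnet.example/nested#X1"/>
  </bp:BiochemicalReaction>
  <bp:Protein rdf:about="http://biopaxnet.example/nested#X1">
    <bp:displayName>Metabolite-like protein one</bp:displayName>
  </bp:Protein>
  <bp:Protein rdf:about="http://biopaxnet.example/nested#X2">
    <bp:displayName>Metabolite-like protein two</bp:displayName>
  </bp:Protein>
  <bp:Protein rdf:about="http://biopaxnet.example/nested#X3">
    <bp:displayName>Metabolite-like protein three</bp:displayName>
  </bp:Protein>
</rdf:RDF>
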