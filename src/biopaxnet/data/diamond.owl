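<?xml version="1.0" encoding="UTF-8"?>
<!-- Control/conversion topology whose graph is a diamond: two enzymes
     E1, E2 catalyse (via C1, C2) the same reaction R converting A to B.
     Downstream traversal gives E1 -> C1 -> R -> B and E2 -> C2 -> R -> B,
     so the common downstream of {E1, E2} is {R, B}. -->
<rdf:RDF xmlns:rdf="http://www.w3.org/1999/02/22-rdf-syntax-ns#"
         xmlns:owl="http://www.w3.org/2002/07/owl#"
         xmlns:bp="http://www.biopax.org/release/biopax-level3.owl#">
  <owl:Ontology rdf:about="http://biopaxnet.example/diamond">
    <owl:imports rdf:resource="http://www.biopax.org/release/biopax-level3.owl"/>
  </owl:Ontology>
  <bp:Protein rdf:about="http://biopaxnet.example/diamond#E1">
    <bp:displayName>Enzyme one</bp:displayName>
  </bp:Protein>
  <bp:Protein rdf:about="http://biopaxnet.example/diamond#E2">
    <bp:displayName>Enzyme two</bp:displayName>
  </bp:Protein>
  <bp:Protein rdf:about="http://biopaxnet.example/diamond#A">
    <bp:displayName>Substrate</bp:displayName>
  </bp:Protein>
  <bp:Protein rdf:about="http://biopaxnet.example/diamond#B">
    <bp:displayName>Product</bp:displayName>
  </bp:Protein>
  <bp:BiochemicalReaction rdf:about="http://biopaxnet.example/diamond#R">
    <bp:displayName>A to B conversion</bp:displayName>
    <bp:left rdf:resource="http://biopaxnet.example/diamond#A"/>
    <bp:right rdf:resource="http://biopaxnet.example/diamond#B"/>
  </bp:BiochemicalReaction>
  <bp:Catalysis rdf:about="http://biopaxnet.example/diamond#C1">
    <bp:controller rdf:resource="http://biopaxnet.example/diamond#E1"/>
    <bp:controlled rdf:resource="http://biopaxnet.example/diamond#R"/>
  </bp:Catalysis>
  <bp:Catalysis rdf:about="http://biopaxnet.example/diamond#C2">
    <bp:controller rdf:resource="http://biopaxnet.example/diamond#E2"/>
    <bp:controlled rdf:resource="http://biopaxnet.example/diamond#R"/>
  </bp:Catalysis>
</rdf:RDF>
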