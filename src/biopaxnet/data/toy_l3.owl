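<?xml version="1.0" encoding="UTF-8"?>
<!-- Hand-authored toy pathway, BioPAX Level 3: one pathway with two
     biochemical reactions over four proteins, one two-member complex,
     and three protein references (P4 shares PR3 with P3). -->
<rdf:RDF xmlns:rdf="http://www.w3.org/1999/02/22-rdf-syntax-ns#"
         xmlns:owl="http://www.w3.org/2002/07/owl#"
         xmlns:bp="http://www.biopax.org/release/biopax-level3.owl#">
  <owl:Ontology rdf:about="http://biopaxnet.example/toy">
    <owl:imports rdf:resource="http://www.biopax.org/release/biopax-level3.owl"/>
  </owl:Ontology>
  <bp:Pathway rdf:about="http://biopaxnet.example/toy#Pathway1">
    <bp:displayName>Toy signalling pathway</bp:displayName>
    <bp:pathwayComponent rdf:resource="http://biopaxnet.example/toy#R1"/>
    <bp:pathwayComponent rdf:resource="http://biopaxnet.example/toy#R2"/>
  </bp:Pathway>
  <bp:BiochemicalReaction rdf:about="http://biopaxnet.example/toy#R1">
    <bp:displayName>P1 to P2 conversion</bp:displayName>
    <bp:left rdf:resource="http://biopaxnet.example/toy#P1"/>
    <bp:right rdf:resource="http://biopaxnet.example/toy#P2"/>
  </bp:BiochemicalReaction>
  <bp:BiochemicalReaction rdf:about="http://biopaxnet.example/toy#R2">
    <bp:displayName>Complex formation from P2</bp:displayName>
    <bp:left rdf:resource="http://biopaxnet.example/toy#P2"/>
    <bp:right rdf:resource="http://biopaxnet.example/toy#C1"/>
  </bp:BiochemicalReaction>
  <bp:Protein rdf:about="http://biopaxnet.example/toy#P1">
    <bp:displayName>Protein one</bp:displayName>
    <bp:entityReference rdf:resource="http://biopaxnet.example/toy#PR1"/>
  </bp:Protein>
  <bp:Protein rdf:about="http://biopaxnet.example/toy#P2">
    <bp:displayName>Protein two</bp:displayName>
    <bp:entityReference rdf:resource="http://biopaxnet.example/toy#PR2"/>
  </bp:Protein>
  <bp:Protein rdf:about="http://biopaxnet.example/toy#P3">
    <bp:displayName>Protein three</bp:displayName>
    <bp:entityReference rdf:resource="http://biopaxnet.example/toy#PR3"/>
  </bp:Protein>
  <bp:Protein rdf:about="http://biopaxnet.example/toy#P4">
    <bp:displayName>Protein four</bp:displayName>
    <bp:entityReference rdf:resource="http://biopaxnet.example/toy#PR3"/>
  </bp:Protein>
  <bp:Complex rdf:about="http://biopaxnet.example/toy#C1">
    <bp:displayName>P3-P4 complex</bp:displayName>
    <bp:component rdf:resource="http://biopaxnet.example/toy#P3"/>
    <bp:component rdf:resource="http://biopaxnet.example/toy#P4"/>
  </bp:Complex>
  <bp:ProteinReference rdf:about="http://biopaxnet.example/toy#PR1">
    <bp:displayName>Reference for P1</bp:displayName>
  </bp:ProteinReference>
  <bp:ProteinReference rdf:about="http://biopaxnet.example/toy#PR2">
    <bp:displayName>Reference for P2</bp:displayName>
  </bp:ProteinReference>
  <bp:ProteinReference rdf:about="http://biopaxnet.example/toy#PR3">
    <bp:displayName>Shared reference for P3 and P4</bp:displayName>
  </bp:ProteinReference>
</rdf:RDF>
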