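<?xml version="1.0" encoding="UTF-8"?>
<!-- The same toy pathway authored in BioPAX Level 2: interactions and
     complex components go through physicalEntityParticipant wrappers,
     which the Level 3 upgrade collapses. -->
<rdf:RDF xmlns:rdf="http://www.w3.org/1999/02/22-rdf-syntax-ns#"
         xmlns:owl="http://www.w3.org/2002/07/owl#"
         xmlns:bp="http://www.biopax.org/release/biopax-level2.owl#">
  <owl:Ontology rdf:about="http://biopaxnet.example/toy">
    <owl:imports rdf:resource="http://www.biopax.org/release/biopax-level2.owl"/>
  </owl:Ontology>
  <bp:pathway rdf:about="http://biopaxnet.example/toy#Pathway1">
    <bp:NAME>Toy signalling pathway</bp:NAME>
    <bp:PATHWAY-COMPONENTS rdf:resource="http://biopaxnet.example/toy#R1"/>
    <bp:PATHWAY-COMPONENTS rdf:resource="http://biopaxnet.example/toy#R2"/>
  </bp:pathway>
  <bp:biochemicalReaction rdf:about="http://biopaxnet.example/toy#R1">
    <bp:NAME>P1 to P2 conversion</bp:NAME>
    <bp:LEFT rdf:resource="http://biopaxnet.example/toy#pep1"/>
    <bp:RIGHT rdf:resource="http://biopaxnet.example/toy#pep2"/>
  </bp:biochemicalReaction>
  <bp:biochemicalReaction rdf:about="http://biopaxnet.example/toy#R2">
    <bp:NAME>Complex formation from P2</bp:NAME>
    <bp:LEFT rdf:resource="http://biopaxnet.example/toy#pep3"/>
    <bp:RIGHT rdf:resource="http://biopaxnet.example/toy#pep4"/>
  </bp:biochemicalReaction>
  <bp:physicalEntityParticipant rdf:about="http://biopaxnet.example/toy#pep1">
    <bp:PHYSICAL-ENTITY rdf:resource="http://biopaxnet.example/toy#P1"/>
  </bp:physicalEntityParticipant>
  <bp:physicalEntityParticipant rdf:about="http://biopaxnet.example/toy#pep2">
    <bp:PHYSICAL-ENTITY rdf:resource="http://biopaxnet.example/toy#P2"/>
  </bp:physicalEntityParticipant>
  <bp:physicalEntityParticipant rdf:about="http://biopaxnet.example/toy#pep3">
    <bp:PHYSICAL-ENTITY rdf:resource="http://biopaxnet.example/toy#P2"/>
  </bp:physicalEntityParticipant>
  <bp:physicalEntityParticipant rdf:about="http://biopaxnet.example/toy#pep4">
    <bp:PHYSICAL-ENTITY rdf:resource="http://biopaxnet.example/toy#C1"/>
  </bp:physicalEntityParticipant>
  <bp:physicalEntityParticipant rdf:about="http://biopaxnet.example/toy#pep5">
    <bp:PHYSICAL-ENTITY rdf:resource="http://biopaxnet.example/toy#P3"/>
  </bp:physicalEntityParticipant>
  <bp:physicalEntityParticipant rdf:about="http://biopaxnet.example/toy#pep6">
    <bp:PHYSICAL-ENTITY rdf:resource="http://biopaxnet.example/toy#P4"/>
  </bp:physicalEntityParticipant>
  <bp:protein rdf:about="http://biopaxnet.example/toy#P1">
    <bp:NAME>Protein one</bp:NAME>
  </bp:protein>
  <bp:protein rdf:about="http://biopaxnet.example/toy#P2">
    <bp:NAME>Protein two</bp:NAME>
  </bp:protein>
  <bp:protein rdf:about="http://biopaxnet.example/toy#P3">
    <bp:NAME>Protein three</bp:NAME>
  </bp:protein>
  <bp:protein rdf:about="http://biopaxnet.example/toy#P4">
    <bp:NAME>Protein four</bp:NAME>
  </bp:protein>
  <bp:complex rdf:about="http://biopaxnet.example/toy#C1">
    <bp:NAME>P3-P4 complex</bp:NAME>
    <bp:COMPONENTS rdf:resource="http://biopaxnet.example/toy#pep5"/>
    <bp:COMPONENTS rdf:resource="http://biopaxnet.example/toy#pep6"/>
  </bp:complex>
</rdf:RDF>
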