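# Glyph style table: BioPAX type -> mEPN-derived 2D glyph, 3D solid, colour.
# Types absent from this table inherit the style of their nearest styled
# ancestor in the supported hierarchy.  The scheme follows the modified
# Edinburgh Pathway Notation conventions where an equivalent concept
# exists; concepts without an mEPN analogue received dedicated glyphs
# (the dumbbell for RNA regions, a generic control glyph for Control).
Element:
  shape2d: ellipse
  shape3d: sphere
  colour: "#BBBBBB"
Pathway:
  shape2d: vertical-banner
  shape3d: cube
  colour: "#C89BDE"
Interaction:
  shape2d: diamond
  shape3d: octahedron
  colour: "#B0B0B0"
Conversion:
  shape2d: square
  shape3d: cube
  colour: "#808080"
BiochemicalReaction:
  shape2d: square
  shape3d: cube
  colour: "#4D4D4D"
ComplexAssembly:
  shape2d: square
  shape3d: cube
  colour: "#6E6E6E"
Transport:
  shape2d: square
  shape3d: cube
  colour: "#8A6E4B"
TemplateReaction:
  shape2d: square
  shape3d: cube
  colour: "#9E9E50"
MolecularInteraction:
  shape2d: diamond
  shape3d: octahedron
  colour: "#7F9FB0"
GeneticInteraction:
  shape2d: diamond
  shape3d: octahedron
  colour: "#B07FA0"
Control:
  shape2d: generic-control
  shape3d: cone
  colour: "#E0A040"
Catalysis:
  shape2d: catalysis-circle
  shape3d: cone
  colour: "#40A040"
PhysicalEntity:
  shape2d: rounded-rectangle
  shape3d: rounded-cube
  colour: "#A0C8E8"
Protein:
  shape2d: rounded-rectangle
  shape3d: rounded-cube
  colour: "#3399DD"
Complex:
  shape2d: octagon
  shape3d: dodecahedron
  colour: "#2255AA"
SmallMolecule:
  shape2d: ion-simple-molecule
  shape3d: sphere
  colour: "#EE8833"
Dna:
  shape2d: parallelogram
  shape3d: cylinder
  colour: "#55AA55"
Rna:
  shape2d: parallelogram
  shape3d: cylinder
  colour: "#AA55AA"
RnaRegion:
  shape2d: dumbbell
  shape3d: capsule
  colour: "#CC77CC"
Gene:
  shape2d: hexagon
  shape3d: prism
  colour: "#77AA33"
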