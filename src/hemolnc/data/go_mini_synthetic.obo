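format-version: 1.2
ontology: go-mini-synthetic
remark: Synthetic miniature GO subset (is_a edges only) used by the synthetic-data generator and tests; term ids reuse real GO accessions for the three roots and a small immune-flavoured subtree, but the DAG is a hand-built stand-in, not the real ontology.

[Term]
id: GO:0008150
name: biological_process
namespace: biological_process

[Term]
id: GO:0003674
name: molecular_function
namespace: molecular_function

[Term]
id: GO:0005575
name: cellular_component
namespace: cellular_component

[Term]
id: GO:0002376
name: immune system process
namespace: biological_process
is_a: GO:0008150

[Term]
id: GO:0006952
name: defense response
namespace: biological_process
is_a: GO:0008150

[Term]
id: GO:0045087
name: innate immune response
namespace: biological_process
is_a: GO:0002376
is_a: GO:0006952

[Term]
id: GO:0032496
name: response to lipopolysaccharide
namespace: biological_process
is_a: GO:0006952

[Term]
id: GO:0043331
name: response to dsRNA
namespace: biological_process
is_a: GO:0006952

[Term]
id: GO:0061844
name: antimicrobial humoral immune response
namespace: biological_process
is_a: GO:0045087

[Term]
id: GO:0006909
name: phagocytosis
namespace: biological_process
is_a: GO:0002376

[Term]
id: GO:0008152
name: metabolic process
namespace: biological_process
is_a: GO:0008150

[Term]
id: GO:0006412
name: translation
namespace: biological_process
is_a: GO:0008152

[Term]
id: GO:0006508
name: proteolysis
namespace: biological_process
is_a: GO:0008152

[Term]
id: GO:0007165
name: signal transduction
namespace: biological_process
is_a: GO:0008150

[Term]
id: GO:0007166
name: cell surface receptor signaling pathway
namespace: biological_process
is_a: GO:0007165

[Term]
id: GO:0002755
name: MyD88-dependent toll-like receptor signaling pathway
namespace: biological_process
is_a: GO:0007166

[Term]
id: GO:0006915
name: apoptotic process
namespace: biological_process
is_a: GO:0008150

[Term]
id: GO:0006355
name: regulation of transcription, DNA-templated
namespace: biological_process
is_a: GO:0008150

[Term]
id: GO:0016192
name: vesicle-mediated transport
namespace: biological_process
is_a: GO:0008150

[Term]
id: GO:0003824
name: catalytic activity
namespace: molecular_function
is_a: GO:0003674

[Term]
id: GO:0016787
name: hydrolase activity
namespace: molecular_function
is_a: GO:0003824

[Term]
id: GO:0008233
name: peptidase activity
namespace: molecular_function
is_a: GO:0016787

[Term]
id: GO:0005488
name: binding
namespace: molecular_function
is_a: GO:0003674

[Term]
id: GO:0003676
name: nucleic acid binding
namespace: molecular_function
is_a: GO:0005488

[Term]
id: GO:0003723
name: RNA binding
namespace: molecular_function
is_a: GO:0003676

[Term]
id: GO:0003700
name: DNA-binding transcription factor activity
namespace: molecular_function
is_a: GO:0003676

[Term]
id: GO:0004888
name: transmembrane signaling receptor activity
namespace: molecular_function
is_a: GO:0005488

[Term]
id: GO:0005576
name: extracellular region
namespace: cellular_component
is_a: GO:0005575

[Term]
id: GO:0005737
name: cytoplasm
namespace: cellular_component
is_a: GO:0005575

[Term]
id: GO:0005634
name: nucleus
namespace: cellular_component
is_a: GO:0005575

[Term]
id: GO:0005886
name: plasma membrane
namespace: cellular_component
is_a: GO:0005575

[Term]
id: GO:0005840
name: ribosome
namespace: cellular_component
is_a: GO:0005737
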