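gene_symbol	aspect	go_id	term
SEMG1	cellular_component	GO:0005576	extracellular region
SEMG1	biological_process	GO:0000003	reproduction
SEMG1	molecular_function	GO:0005488	binding
SEMG2	cellular_component	GO:0005576	extracellular region
SEMG2	biological_process	GO:0000003	reproduction
SEMG2	molecular_function	GO:0005488	binding
FN1	cellular_component	GO:0005576	extracellular region
FN1	cellular_component	GO:0031012	extracellular matrix
FN1	biological_process	GO:0007155	cell adhesion
FN1	biological_process	GO:0006950	response to stress
FN1	molecular_function	GO:0005488	binding
KLK3	cellular_component	GO:0005576	extracellular region
KLK3	biological_process	GO:0006508	proteolysis
KLK3	biological_process	GO:0000003	reproduction
KLK3	molecular_function	GO:0008233	peptidase activity
KLK3	molecular_function	GO:0003824	catalytic activity
CLU	cellular_component	GO:0005576	extracellular region
CLU	cellular_component	GO:0031983	vesicle lumen
CLU	biological_process	GO:0006950	response to stress
CLU	biological_process	GO:0050789	regulation of biological process
CLU	molecular_function	GO:0005488	binding
MIF	cellular_component	GO:0005576	extracellular region
MIF	cellular_component	GO:0005737	cytoplasm
MIF	biological_process	GO:0006950	response to stress
MIF	biological_process	GO:0050789	regulation of biological process
MIF	molecular_function	GO:0003824	catalytic activity
MIF	molecular_function	GO:0016209	antioxidant activity
LGALS3BP	cellular_component	GO:0005576	extracellular region
LGALS3BP	cellular_component	GO:0031983	vesicle lumen
LGALS3BP	biological_process	GO:0002376	immune system process
LGALS3BP	biological_process	GO:0050789	regulation of biological process
LGALS3BP	molecular_function	GO:0005488	binding
ALB	cellular_component	GO:0005576	extracellular region
ALB	biological_process	GO:0006810	transport
ALB	molecular_function	GO:0005488	binding
ALB	molecular_function	GO:0016209	antioxidant activity
CST4	cellular_component	GO:0005576	extracellular region
CST4	biological_process	GO:0050789	regulation of biological process
CST4	molecular_function	GO:0030234	enzyme regulator activity
LTF	cellular_component	GO:0005576	extracellular region
LTF	biological_process	GO:0006950	response to stress
LTF	biological_process	GO:0002376	immune system process
LTF	molecular_function	GO:0005488	binding
LTF	molecular_function	GO:0008233	peptidase activity
AZGP1	cellular_component	GO:0005576	extracellular region
AZGP1	biological_process	GO:0002376	immune system process
AZGP1	biological_process	GO:0008152	metabolic process
AZGP1	molecular_function	GO:0005488	binding
PIP	cellular_component	GO:0005576	extracellular region
PIP	biological_process	GO:0050789	regulation of biological process
PIP	molecular_function	GO:0003824	catalytic activity
ACPP	cellular_component	GO:0005576	extracellular region
ACPP	biological_process	GO:0008152	metabolic process
ACPP	molecular_function	GO:0003824	catalytic activity
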