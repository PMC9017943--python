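text,diagnosis
breast_cancer,breast_cancer
breast cancer,breast_cancer
breast,breast_cancer
cancer du sein,breast_cancer
sein,breast_cancer
lung_cancer,lung_cancer
lung cancer,lung_cancer
lung,lung_cancer
cancer du poumon,lung_cancer
poumon,lung_cancer
nsclc,lung_cancer
cbnpc,lung_cancer
other,other
autre,other
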