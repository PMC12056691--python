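accession	protein_name
P02768	Albumin
P02787	Serotransferrin
P00738	Haptoglobin
P01876-1	Isoform 1 of Immunoglobulin heavy constant alpha 1
P02671	Fibrinogen alpha chain
P02675	Fibrinogen beta chain
P01024	Complement C3
P02679	Fibrinogen gamma chain
P02647	Apolipoprotein A-I
P02790	Hemopexin
P02652	Apolipoprotein A-II
P02774	Vitamin D-binding protein
P01023	Alpha-2-macroglobulin
P01860	Immunoglobulin heavy constant gamma 3
P02765	Alpha-2-HS-glycoprotein
P08603	Complement factor H
P01871-1	Isoform 1 of Immunoglobulin heavy constant mu
P00450	Ceruloplasmin
P00751	Complement factor B
P01857-1	Isoform 1 of Immunoglobulin heavy constant gamma 1
P01042-2	Isoform LMW of Kininogen-1
P0DOX7	Immunoglobulin kappa light chain
P02763	Alpha-1-acid glycoprotein 1
P00747	Plasminogen
P04217	Alpha-1B-glycoprotein
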