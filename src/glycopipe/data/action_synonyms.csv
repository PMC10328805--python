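synonym,action
agonist,agonist
partial agonist,agonist
full agonist,agonist
activator,activator
inducer,activator
positive allosteric modulator,activator
stimulator,activator
antagonist,antagonist
inverse agonist,antagonist
inhibitor,inhibitor
suppressor,inhibitor
negative allosteric modulator,inhibitor
blocker,blocker
channel blocker,blocker
pore blocker,blocker
binder,other
modulator,other
ligand,other
substrate,other
unknown,other
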